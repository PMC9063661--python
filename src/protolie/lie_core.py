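"""The LIE model: prediction, least-squares calibration, and validation.

The linear interaction energy (LIE) estimate of the binding free energy of a
ligand is

    dG = alpha * (<V_vdw>_bound - <V_vdw>_free)
       + beta  * (<V_elec>_bound - <V_elec>_free) + gamma

where <V>_bound / <V>_free are average ligand–surroundings interaction
energies from simulations of the complex and of the free ligand in solvent,
alpha and beta scale the nonpolar and polar terms, and gamma is a constant
offset (kcal/mol).  This module fits (alpha, beta, gamma) to experimental
affinities by ordinary least squares, applies a fixed parameter set to new
complexes, and scores predictions by Pearson correlation and standard error.

Sign convention: more negative dG means stronger binding.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Gas constant in kcal mol^-1 K^-1.
R_GAS_KCAL = 1.98720425e-3

#: Default absolute temperature (K) for Ki -> dG conversion.
DEFAULT_TEMPERATURE = 300.0

#: Condition-number threshold above which the design matrix is treated as
#: collinear and the fit refused.
COLLINEARITY_THRESHOLD = 1e10


@dataclass(frozen=True)
class LIEParameters:
    """LIE coefficients: nonpolar scaling, polar scaling, constant offset."""

    alpha: float
    beta: float
    gamma: float  # kcal/mol

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"LIEParameters.{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma], dtype=float)

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta, "gamma": self.gamma}


#: Literature "standard" LIE parameters (alpha=0.18, beta=0.5, no offset),
#: derived for globular proteins with a well-defined binding site.  They serve
#: as a negative control for the protofibril system.
STANDARD_PARAMETERS = LIEParameters(0.18, 0.5, 0.0)

#: Parameter set calibrated for the 12-mer amyloid-beta(11-40) protofibril.
ABETA_PARAMETERS = LIEParameters(0.288, -0.049, -5.880)


@dataclass(frozen=True)
class ComplexEnergies:
    """The four averaged ligand–surroundings energies for one complex.

    vdw_* and elec_* are time-averaged van der Waals and electrostatic
    interaction energies (kcal/mol) of the ligand with its surroundings in the
    bound (solvated complex) and free (ligand in water) states.
    """

    ligand_id: str
    vdw_bound: float
    vdw_free: float
    elec_bound: float
    elec_free: float

    def __post_init__(self) -> None:
        for name in ("vdw_bound", "vdw_free", "elec_bound", "elec_free"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"ComplexEnergies.{name} must be finite")


@dataclass(frozen=True)
class AffinityRecord:
    """Experimental affinity of one ligand.

    Either the inhibition constant ``ki`` (molar) or the binding free energy
    ``dg_exp`` (kcal/mol) must be present.  When both are given they must be
    mutually consistent through ``ki_to_dg`` at ``temperature``.
    """

    ligand_id: str
    dg_exp: float | None = None
    ki: float | None = None
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.dg_exp is None and self.ki is None:
            raise ValueError(f"{self.ligand_id}: need ki or dg_exp")
        if self.ki is not None and self.ki <= 0:
            raise ValueError(f"{self.ligand_id}: ki must be positive")
        if self.dg_exp is not None and not math.isfinite(self.dg_exp):
            raise ValueError(f"{self.ligand_id}: dg_exp must be finite")
        if self.dg_exp is not None and self.ki is not None:
            implied = ki_to_dg(self.ki, self.temperature)
            if abs(implied - self.dg_exp) > 0.05:
                raise ValueError(
                    f"{self.ligand_id}: dg_exp={self.dg_exp:.3f} inconsistent "
                    f"with ki ({implied:.3f} at {self.temperature} K)"
                )

    @property
    def dg(self) -> float:
        """Experimental dG: dg_exp when given, else converted from ki."""
        if self.dg_exp is not None:
            return self.dg_exp
        return ki_to_dg(self.ki, self.temperature)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a LIE fit or evaluation against experimental affinities."""

    params: LIEParameters
    r: float
    se: float  # kcal/mol
    residuals: tuple[float, ...]  # predicted - experimental, per ligand
    n: int
    se_definition: str  # "rmse" or "dof_corrected"
    ligand_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.residuals) != self.n:
            raise ValueError("residuals length must equal n")
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("Pearson r outside [-1, 1]")
        if self.se < 0:
            raise ValueError("standard error must be >= 0")

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "r": self.r,
            "se": self.se,
            "se_definition": self.se_definition,
            "n": self.n,
            "residuals": dict(zip(self.ligand_ids, self.residuals))
            if self.ligand_ids
            else list(self.residuals),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass(frozen=True)
class MethodColumn:
    """Per-ligand predicted dG column of one affinity method (e.g. FEP)."""

    method: str
    ligand_ids: tuple[str, ...]
    dg_pred: tuple[float, ...]  # kcal/mol

    def __post_init__(self) -> None:
        if len(self.ligand_ids) != len(self.dg_pred):
            raise ValueError("ligand_ids and dg_pred lengths differ")
        if not all(math.isfinite(v) for v in self.dg_pred):
            raise ValueError(f"{self.method}: non-finite predictions")


@dataclass(frozen=True)
class MethodComparison:
    method: str
    r: float
    se: float  # rmse vs experiment, kcal/mol
    n: int


def ki_to_dg(ki: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert an inhibition constant (molar) to dG = R*T*ln(Ki), kcal/mol.

    Uses the 1 M standard state, so Ki = 1 M maps to dG = 0.
    """
    if ki <= 0:
        raise ValueError("ki must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_GAS_KCAL * temperature * math.log(ki)


def delta_energies(ce: ComplexEnergies) -> tuple[float, float]:
    """Bound-minus-free energy differences (d_vdw, d_elec), kcal/mol."""
    return ce.vdw_bound - ce.vdw_free, ce.elec_bound - ce.elec_free


def lie_predict(ce: ComplexEnergies, p: LIEParameters) -> float:
    """Predicted binding free energy (kcal/mol) of one complex."""
    d_vdw, d_elec = delta_energies(ce)
    return p.alpha * d_vdw + p.beta * d_elec + p.gamma


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def standard_error(
    residuals: Sequence[float], n_params: int = 0, definition: str = "rmse"
) -> float:
    """Residual spread in kcal/mol.

    ``rmse`` divides the residual sum of squares by n; ``dof_corrected``
    divides by (n - n_params).  The latter is the unbiased estimator when
    n_params coefficients were fitted on the same data.
    """
    r = np.asarray(residuals, dtype=float)
    if definition == "rmse":
        if r.size == 0:
            raise ValueError("need at least one residual")
        return float(np.sqrt(np.mean(r**2)))
    if definition == "dof_corrected":
        if r.size <= n_params:
            raise ValueError("need more residuals than fitted parameters")
        return float(np.sqrt(np.sum(r**2) / (r.size - n_params)))
    raise ValueError(f"unknown se definition: {definition!r}")


def _design(dataset) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    ids = []
    rows = []
    y = []
    for ce, aff in dataset:
        if ce.ligand_id != aff.ligand_id:
            raise ValueError(
                f"ligand_id mismatch: {ce.ligand_id!r} vs {aff.ligand_id!r}"
            )
        d_vdw, d_elec = delta_energies(ce)
        rows.append((d_vdw, d_elec, 1.0))
        y.append(aff.dg)
        ids.append(ce.ligand_id)
    return np.asarray(rows), np.asarray(y), tuple(ids)


def fit_lie(dataset, se_definition: str = "rmse") -> FitResult:
    """Fit (alpha, beta, gamma) by ordinary least squares.

    ``dataset`` is a sequence of (ComplexEnergies, AffinityRecord) pairs with
    matching ligand ids.  gamma is fitted as a free intercept.  The reported
    Pearson r correlates fitted predictions with experiment; the standard
    error follows ``se_definition`` (3 fitted parameters for dof_corrected).
    """
    dataset = list(dataset)
    n = len(dataset)
    if n < 4:
        raise ValueError(f"need >= 4 complexes to fit 3 parameters, got {n}")
    X, y, ids = _design(dataset)
    if np.linalg.cond(X) > COLLINEARITY_THRESHOLD:
        raise ValueError("collinear predictors: singular LIE design matrix")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    params = LIEParameters(*coef)
    pred = X @ coef
    resid = pred - y
    n_params = 3 if se_definition == "dof_corrected" else 0
    return FitResult(
        params=params,
        r=pearson_r(pred, y),
        se=standard_error(resid, n_params=n_params, definition=se_definition),
        residuals=tuple(resid),
        n=n,
        se_definition=se_definition,
        ligand_ids=ids,
    )


def evaluate(dataset, p: LIEParameters, se_definition: str = "rmse") -> FitResult:
    """Score a fixed parameter set on a dataset without refitting.

    The standard error uses n_params = 0 regardless of definition: the
    parameters were not estimated on this set.
    """
    dataset = list(dataset)
    if len(dataset) < 3:
        raise ValueError("need >= 3 complexes to evaluate")
    X, y, ids = _design(dataset)
    pred = X @ p.as_array()
    resid = pred - y
    return FitResult(
        params=p,
        r=pearson_r(pred, y),
        se=standard_error(resid, n_params=0, definition=se_definition),
        residuals=tuple(resid),
        n=len(dataset),
        se_definition=se_definition,
        ligand_ids=ids,
    )


def compare_methods(
    columns: Iterable[MethodColumn], exp: Iterable[AffinityRecord]
) -> list[MethodComparison]:
    """Correlate each method's dG column with experiment.

    Records are joined on exact ligand_id; each method needs >= 3 ligands in
    common with the experimental records.  Returns one MethodComparison per
    method (Pearson r and RMSE), sorted best-correlating first.
    """
    exp_by_id = {a.ligand_id: a.dg for a in exp}
    out = []
    for col in columns:
        pred, obs = [], []
        for lid, dg in zip(col.ligand_ids, col.dg_pred):
            if lid in exp_by_id:
                pred.append(dg)
                obs.append(exp_by_id[lid])
        if len(pred) < 3:
            raise ValueError(
                f"method {col.method!r}: only {len(pred)} ligands align with "
                "experimental records (need >= 3)"
            )
        resid = np.asarray(pred) - np.asarray(obs)
        out.append(
            MethodComparison(
                method=col.method,
                r=pearson_r(pred, obs),
                se=standard_error(resid, definition="rmse"),
                n=len(pred),
            )
        )
    out.sort(key=lambda m: m.r, reverse=True)
    return out


def random_split(dataset, n_train: int, seed: int):
    """Deterministic random partition into (train, test) of sizes (n_train, n - n_train)."""
    dataset = list(dataset)
    n = len(dataset)
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")
    order = np.random.default_rng(seed).permutation(n)
    train = [dataset[i] for i in order[:n_train]]
    test = [dataset[i] for i in order[n_train:]]
    return train, test


def read_method_table(path) -> tuple[list[MethodColumn], list[AffinityRecord]]:
    """Read a method-comparison CSV: ligand_id,dg_exp,dg_<method>,... (kcal/mol)."""
    df = pd.read_csv(path)
    required = {"ligand_id", "dg_exp"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    ids = tuple(str(i) for i in df["ligand_id"])
    exp = [
        AffinityRecord(ligand_id=lid, dg_exp=float(dg))
        for lid, dg in zip(ids, df["dg_exp"])
    ]
    columns = []
    for col in df.columns:
        if col.startswith("dg_") and col != "dg_exp":
            columns.append(
                MethodColumn(
                    method=col[3:],
                    ligand_ids=ids,
                    dg_pred=tuple(float(v) for v in df[col]),
                )
            )
    if not columns:
        warnings.warn(f"{path}: no dg_<method> columns found")
    return columns, exp
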