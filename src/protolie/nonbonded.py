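"""Desk-scale pairwise Lennard-Jones + Coulomb interaction energies.

Computes ligand–surroundings van der Waals and electrostatic energies from
coordinates and per-atom parameters, so the whole LIE pipeline can be
exercised end-to-end on toy systems without a molecular-dynamics engine.
Electrostatics are plain truncated Coulomb at the van der Waals cutoff
(10 A default); there is no Ewald/PME, no switching function, and no bonded
or 1-4 machinery — ligand and environment are distinct molecules, so every
cross pair interacts at full strength.  Lorentz–Berthelot combination rules
(arithmetic sigma, geometric epsilon) are used throughout.

Units: coordinates and cutoffs in Angstrom, charges in elementary charge
units, epsilon and energies in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .energy_io import Component, EnergyTrace, State

#: Coulomb constant in kcal A mol^-1 e^-2.
COULOMB_CONSTANT = 332.0636

#: Default interaction cutoff (A), matching a 1.0 nm vdW cutoff.
DEFAULT_CUTOFF = 10.0

#: Interatomic distances below this (A) are treated as overlapping atoms.
OVERLAP_DISTANCE = 1e-6


class OverlapError(ValueError):
    """Two atoms closer than OVERLAP_DISTANCE; carries the offending pair."""

    def __init__(self, i: int, j: int, r: float):
        self.pair = (i, j)
        super().__init__(
            f"atoms {i} and {j} overlap (r = {r:.3e} A < {OVERLAP_DISTANCE} A)"
        )


@dataclass(frozen=True)
class AtomParameters:
    charge: float  # e
    sigma: float  # A
    epsilon: float  # kcal/mol

    def __post_init__(self) -> None:
        if not math.isfinite(self.charge):
            raise ValueError("charge must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass(frozen=True)
class Topology:
    """Atom parameters plus the ligand/environment partition."""

    atoms: tuple[AtomParameters, ...]
    ligand_indices: frozenset[int]
    environment_indices: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        lig = frozenset(self.ligand_indices)
        env = frozenset(self.environment_indices)
        object.__setattr__(self, "ligand_indices", lig)
        object.__setattr__(self, "environment_indices", env)
        n = len(self.atoms)
        if not lig or not env:
            raise ValueError("ligand and environment index sets must be non-empty")
        if lig & env:
            raise ValueError("ligand and environment index sets overlap")
        if any(i < 0 or i >= n for i in lig | env):
            raise ValueError("atom index out of bounds")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class Frame:
    """One coordinate snapshot; ``box`` enables orthorhombic minimum image."""

    coordinates: np.ndarray  # (n, 3), A
    box: np.ndarray | None = None  # (3,) box lengths, A
    time: float = 0.0  # ns

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("coordinates must have shape (n, 3)")
        if not np.all(np.isfinite(c)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coordinates", c)
        if self.box is not None:
            b = np.asarray(self.box, dtype=float)
            if b.shape != (3,) or np.any(b <= 0):
                raise ValueError("box must be three positive lengths")
            object.__setattr__(self, "box", b)


def lj_pair(eps_i: float, eps_j: float, sig_i: float, sig_j: float, r) -> float:
    """12-6 Lennard-Jones energy with Lorentz–Berthelot combination.

    eps_ij = sqrt(eps_i * eps_j), sig_ij = (sig_i + sig_j) / 2;
    U = 4 eps_ij [(sig_ij/r)^12 - (sig_ij/r)^6].
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    eps = math.sqrt(eps_i * eps_j)
    sig = 0.5 * (sig_i + sig_j)
    sr6 = (sig / r) ** 6
    out = 4.0 * eps * (sr6**2 - sr6)
    return float(out) if out.ndim == 0 else out


def coulomb_pair(q_i: float, q_j: float, r) -> float:
    """Coulomb energy k_e q_i q_j / r in kcal/mol."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    out = COULOMB_CONSTANT * q_i * q_j / r
    return float(out) if out.ndim == 0 else out


def interaction_energy(
    top: Topology, frame: Frame, cutoff: float = DEFAULT_CUTOFF
) -> tuple[float, float]:
    """Ligand–environment (vdw, elec) energies in kcal/mol.

    Sums all ligand x environment pairs with r <= cutoff (inclusive, hard
    truncation); minimum-image distances when the frame has a box.  No
    intra-ligand or intra-environment pairs are included.  Raises
    OverlapError when two interacting atoms nearly coincide.
    """
    coords = frame.coordinates
    if coords.shape[0] != top.n_atoms:
        raise ValueError(
            f"frame has {coords.shape[0]} atoms, topology {top.n_atoms}"
        )
    if frame.box is not None and np.any(frame.box <= 2 * cutoff):
        raise ValueError("box lengths must exceed 2 x cutoff for minimum image")
    lig = np.array(sorted(top.ligand_indices), dtype=int)
    env = np.array(sorted(top.environment_indices), dtype=int)
    diff = coords[lig][:, None, :] - coords[env][None, :, :]
    if frame.box is not None:
        diff -= frame.box * np.round(diff / frame.box)
    r = np.sqrt(np.sum(diff**2, axis=-1))
    if np.any(r < OVERLAP_DISTANCE):
        i, j = np.argwhere(r < OVERLAP_DISTANCE)[0]
        raise OverlapError(int(lig[i]), int(env[j]), float(r[i, j]))

    q = np.array([a.charge for a in top.atoms])
    sig = np.array([a.sigma for a in top.atoms])
    eps = np.array([a.epsilon for a in top.atoms])
    mask = r <= cutoff
    if not mask.any():
        return 0.0, 0.0
    eps_ij = np.sqrt(np.outer(eps[lig], eps[env]))
    sig_ij = 0.5 * (sig[lig][:, None] + sig[env][None, :])
    with np.errstate(divide="ignore"):
        sr6 = np.where(mask, (sig_ij / np.where(mask, r, 1.0)) ** 6, 0.0)
    vdw = float(np.sum(4.0 * eps_ij * (sr6**2 - sr6) * mask))
    qq = np.outer(q[lig], q[env])
    elec = float(np.sum(np.where(mask, COULOMB_CONSTANT * qq / np.where(mask, r, 1.0), 0.0)))
    return vdw, elec


def interaction_energy_naive(
    top: Topology, frame: Frame, cutoff: float = DEFAULT_CUTOFF
) -> tuple[float, float]:
    """Reference O(N^2) double loop over explicit pair terms (testing aid)."""
    coords = frame.coordinates
    vdw = elec = 0.0
    for i in sorted(top.ligand_indices):
        for j in sorted(top.environment_indices):
            d = coords[i] - coords[j]
            if frame.box is not None:
                d = d - frame.box * np.round(d / frame.box)
            r = float(np.linalg.norm(d))
            if r < OVERLAP_DISTANCE:
                raise OverlapError(i, j, r)
            if r > cutoff:
                continue
            ai, aj = top.atoms[i], top.atoms[j]
            vdw += lj_pair(ai.epsilon, aj.epsilon, ai.sigma, aj.sigma, r)
            elec += coulomb_pair(ai.charge, aj.charge, r)
    return vdw, elec


def trajectory_energy_series(
    top: Topology,
    frames: Sequence[Frame],
    cutoff: float = DEFAULT_CUTOFF,
    state: State | str = State.BOUND,
    ligand_id: str = "LIG",
    replica_id: int = 1,
) -> tuple[EnergyTrace, EnergyTrace]:
    """Per-frame interaction energies packaged as (vdw, elec) EnergyTraces."""
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    times, vdw, elec = [], [], []
    for k, fr in enumerate(frames):
        try:
            v, e = interaction_energy(top, fr, cutoff)
        except ValueError as err:
            raise ValueError(f"frame {k}: {err}") from err
        times.append(fr.time)
        vdw.append(v)
        elec.append(e)
    return (
        EnergyTrace(times, vdw, Component.VDW, state, replica_id, ligand_id),
        EnergyTrace(times, elec, Component.ELEC, state, replica_id, ligand_id),
    )


def read_topology_csv(path) -> Topology:
    """Read a topology CSV: ``index,charge_e,sigma_A,epsilon_kcal,group``.

    group is "ligand" or "environment"; rows may appear in any index order.
    """
    df = pd.read_csv(path)
    required = {"index", "charge_e", "sigma_A", "epsilon_kcal", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    df = df.sort_values("index")
    if list(df["index"]) != list(range(len(df))):
        raise ValueError(f"{path}: indices must be 0..n-1 without gaps")
    atoms, lig, env = [], set(), set()
    for row in df.itertuples(index=False):
        atoms.append(AtomParameters(row.charge_e, row.sigma_A, row.epsilon_kcal))
        if row.group == "ligand":
            lig.add(int(row.index))
        elif row.group == "environment":
            env.add(int(row.index))
        else:
            raise ValueError(f"{path}: unknown group {row.group!r}")
    return Topology(tuple(atoms), frozenset(lig), frozenset(env))
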