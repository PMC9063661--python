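"""Synthetic fixtures with the statistical structure the analysis assumes.

Three generators cover the pipeline's inputs end to end without any
simulation engine or download:

* ``gen_energy_traces`` — stationary AR(1) series emulating post-
  equilibration interaction-energy time series (autocorrelated noise around
  a fixed mean);
* ``gen_lie_dataset`` — per-ligand averaged energies plus experimental
  affinities drawn from the LIE linear model with Gaussian residuals, so the
  ground-truth (alpha, beta, gamma) is known exactly;
* ``gen_toy_complex`` — small coordinate sets with constructed contact /
  separated / ideal-hydrogen-bond geometries for the structural and
  nonbonded modules.

``write_fixture_bundle`` materialises a complete fixture directory (tables,
traces, toy PDBs, JSON manifest) in either a ``minimal`` or a ``paper_like``
layout (30 ligands, 20/10 split, 4 replicas x 20 ns at 10 ps sampling).

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .energy_io import (
    Component,
    EnergyTrace,
    ReplicaSet,
    State,
    write_complex_table,
    write_xvg,
)
from .lie_core import (
    ABETA_PARAMETERS,
    AffinityRecord,
    ComplexEnergies,
    DEFAULT_TEMPERATURE,
    LIEParameters,
    R_GAS_KCAL,
    random_split,
)
from .nonbonded import AtomParameters, Frame, Topology
from .struct_analysis import AtomRecord, Structure, write_pdb


@dataclass(frozen=True)
class GroundTruth:
    """True generating process for a synthetic LIE study.

    The defaults mirror the protofibril study's regime: the calibrated
    parameter set (0.288, -0.049, -5.880), residuals on the scale of the
    reported standard error (0.95 kcal/mol), van-der-Waals-dominated
    predictor ranges (d_vdw in [-60, -10], d_elec in [-5, +25] kcal/mol,
    i.e. electrostatics weakened on binding), and AR(1) traces with lag-1
    autocorrelation 0.9 at 10 ps sampling.
    """

    params: LIEParameters = ABETA_PARAMETERS
    residual_sd: float = 0.95  # kcal/mol
    ar1_phi: float = 0.9
    trace_sd: float = 2.0  # kcal/mol
    seed: int = 2019
    d_vdw_range: tuple[float, float] = (-60.0, -10.0)
    d_elec_range: tuple[float, float] = (-5.0, 25.0)

    def __post_init__(self) -> None:
        if self.residual_sd < 0 or self.trace_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("ar1_phi must be in [0, 1)")


def gen_energy_traces(
    mean: float,
    trace_sd: float,
    ar1_phi: float,
    n_frames: int,
    dt: float,
    seed: int,
    component: Component | str = Component.VDW,
    state: State | str = State.BOUND,
    replica_id: int = 1,
    ligand_id: str = "LIG",
) -> EnergyTrace:
    """Stationary AR(1) energy trace around ``mean``.

    v_t = mean + phi (v_{t-1} - mean) + eta_t with
    eta ~ N(0, trace_sd^2 (1 - phi^2)) and v_0 ~ N(mean, trace_sd^2), so the
    marginal sd is ``trace_sd`` at every frame and the lag-1 autocorrelation
    is ``ar1_phi``.  Times are 0, dt, 2 dt, ... (ns).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0 <= ar1_phi < 1:
        raise ValueError("ar1_phi must be in [0, 1)")
    if trace_sd < 0:
        raise ValueError("trace_sd must be >= 0")
    times = np.arange(n_frames) * dt
    if trace_sd == 0:
        values = np.full(n_frames, mean)
    else:
        rng = np.random.default_rng(seed)
        x0 = rng.normal(0.0, trace_sd)
        eta = rng.normal(0.0, trace_sd * math.sqrt(1 - ar1_phi**2), n_frames - 1)
        dev = lfilter([1.0], [1.0, -ar1_phi], np.concatenate([[x0], eta]))
        values = mean + dev
    return EnergyTrace(times, values, component, state, replica_id, ligand_id)


def gen_lie_dataset(
    gt: GroundTruth, n_ligands: int
) -> list[tuple[ComplexEnergies, AffinityRecord]]:
    """Per-ligand averaged energies and affinities from the LIE linear model.

    Energy differences are drawn uniformly from ``gt``'s predictor ranges and
    split arbitrarily into bound/free components; the experimental dG is
    alpha d_vdw + beta d_elec + gamma + N(0, residual_sd^2), with a Ki that
    is exactly consistent at 300 K.  Deterministic for a fixed ``gt.seed``.
    """
    if n_ligands < 4:
        raise ValueError("need >= 4 ligands for a fittable dataset")
    rng = np.random.default_rng(gt.seed)
    p = gt.params
    out = []
    for i in range(n_ligands):
        lid = f"LIG{i + 1:03d}"
        d_vdw = rng.uniform(*gt.d_vdw_range)
        d_elec = rng.uniform(*gt.d_elec_range)
        vdw_free = rng.uniform(-15.0, -5.0)
        elec_free = rng.uniform(-25.0, -5.0)
        ce = ComplexEnergies(
            ligand_id=lid,
            vdw_bound=vdw_free + d_vdw,
            vdw_free=vdw_free,
            elec_bound=elec_free + d_elec,
            elec_free=elec_free,
        )
        dg = (
            p.alpha * d_vdw + p.beta * d_elec + p.gamma
            + rng.normal(0.0, gt.residual_sd)
        )
        ki = math.exp(dg / (R_GAS_KCAL * DEFAULT_TEMPERATURE))
        out.append((ce, AffinityRecord(ligand_id=lid, dg_exp=dg, ki=ki)))
    return out


def gen_replica_sets(
    ce: ComplexEnergies,
    gt: GroundTruth,
    n_replicas: int = 4,
    n_frames: int = 2001,
    dt: float = 0.01,
    seed: int | None = None,
) -> dict[tuple[Component, State], ReplicaSet]:
    """AR(1) replica traces whose stationary means are the complex's energies.

    Returns the four ReplicaSets keyed by (component, state), ready for
    ``assemble_complex_energies``.
    """
    rng = np.random.default_rng(gt.seed if seed is None else seed)
    means = {
        (Component.VDW, State.BOUND): ce.vdw_bound,
        (Component.ELEC, State.BOUND): ce.elec_bound,
        (Component.VDW, State.FREE): ce.vdw_free,
        (Component.ELEC, State.FREE): ce.elec_free,
    }
    sets = {}
    for key, mean in means.items():
        comp, state = key
        traces = tuple(
            gen_energy_traces(
                mean,
                gt.trace_sd,
                gt.ar1_phi,
                n_frames,
                dt,
                seed=int(rng.integers(2**31)),
                component=comp,
                state=state,
                replica_id=k + 1,
                ligand_id=ce.ligand_id,
            )
            for k in range(n_replicas)
        )
        sets[key] = ReplicaSet(traces, expected_replicas=n_replicas)
    return sets


# ---------------------------------------------------------------------------
# Toy coordinate systems

_GEOMETRIES = ("contact", "separated", "hbond_ideal")

_ELEMENT_PARAMS = {
    "C": AtomParameters(0.0, 3.4, 0.10),
    "O": AtomParameters(-0.3, 3.0, 0.20),
    "H": AtomParameters(0.3, 1.0, 0.02),
}


def _atom_params(element: str, group: str) -> AtomParameters:
    base = _ELEMENT_PARAMS[element]
    if element == "C":
        # small opposite charges so the electrostatic term is exercised
        return AtomParameters(0.1 if group == "ligand" else -0.1, base.sigma, base.epsilon)
    return base


def gen_toy_complex(
    n_peptide_atoms: int,
    n_ligand_atoms: int,
    geometry: str,
    seed: int = 0,
) -> tuple[Topology, list[Frame], list[Structure]]:
    """Toy peptide+ligand system exercising the contact/HB/energy criteria.

    Peptide atoms sit on a line at 4 A spacing; the ligand placement depends
    on ``geometry``:

    * ``contact`` — ligand C atoms ~3.2 A from peptide atoms (within the
      2.9–3.9 A hydrophobic-contact window); min(n_ligand, n_peptide) atoms
      are in range, any excess sits further out;
    * ``separated`` — the whole ligand is displaced 50 A away (beyond any
      default cutoff);
    * ``hbond_ideal`` — one O-H...O triple with donor–acceptor distance
      2.9 A and a 180-degree A–H–D angle (requires n_ligand_atoms >= 2: the
      donor O and its H are ligand atoms; peptide atom 1 is the acceptor O).

    Returns a consistent (Topology, frames, structures) triple; atom order is
    peptide first, then ligand.
    """
    if geometry not in _GEOMETRIES:
        raise ValueError(f"geometry must be one of {_GEOMETRIES}, got {geometry!r}")
    if n_peptide_atoms < 1 or n_ligand_atoms < 1:
        raise ValueError("atom counts must be >= 1")
    if geometry == "hbond_ideal" and n_ligand_atoms < 2:
        raise ValueError("hbond_ideal needs >= 2 ligand atoms (donor O and H)")
    rng = np.random.default_rng(seed)

    pep_elements = ["C"] * n_peptide_atoms
    pep_names = ["CA"] * n_peptide_atoms
    pep_xyz = np.zeros((n_peptide_atoms, 3))
    pep_xyz[:, 0] = 4.0 * np.arange(n_peptide_atoms)
    # slight zigzag keeps the backbone non-collinear (superposable) without
    # moving any ligand atom out of its intended distance window
    pep_xyz[1::2, 2] = 0.4
    if geometry == "hbond_ideal":
        pep_elements[0] = "O"
        pep_names[0] = "O"

    lig_elements = ["C"] * n_ligand_atoms
    lig_names = [f"C{j + 1}" for j in range(n_ligand_atoms)]
    lig_xyz = np.zeros((n_ligand_atoms, 3))
    if geometry == "hbond_ideal":
        lig_elements[0], lig_names[0] = "O", "O1"
        lig_elements[1], lig_names[1] = "H", "H1"
        lig_xyz[0] = (0.0, 2.9, 0.0)  # donor O, 2.9 A from acceptor
        lig_xyz[1] = (0.0, 2.9 - 0.97, 0.0)  # H on the D-A axis: angle 180
        for j in range(2, n_ligand_atoms):
            k = j - 1  # keep clear of the hydrogen-bond site
            lig_xyz[j] = (4.0 * (1 + (k - 1) % max(n_peptide_atoms - 1, 1)),
                          3.2 + 3.2 * ((k - 1) // max(n_peptide_atoms - 1, 1)),
                          0.0)
    else:
        jitter = rng.uniform(-0.05, 0.05, size=(n_ligand_atoms, 2))
        for j in range(n_ligand_atoms):
            col = j % n_peptide_atoms
            row = j // n_peptide_atoms
            lig_xyz[j] = (4.0 * col + jitter[j, 0], 3.2 + 3.2 * row, jitter[j, 1])
        if geometry == "separated":
            lig_xyz[:, 1] += 50.0

    atoms_params = [
        _atom_params(e, "environment") for e in pep_elements
    ] + [_atom_params(e, "ligand") for e in lig_elements]
    top = Topology(
        atoms=tuple(atoms_params),
        ligand_indices=frozenset(
            range(n_peptide_atoms, n_peptide_atoms + n_ligand_atoms)
        ),
        environment_indices=frozenset(range(n_peptide_atoms)),
    )
    coords = np.vstack([pep_xyz, lig_xyz])
    frames = [Frame(coordinates=coords, time=0.0)]

    records = []
    for i in range(n_peptide_atoms):
        records.append(
            AtomRecord(
                serial=i + 1, name=pep_names[i], element=pep_elements[i],
                res_name="ALA", res_seq=i + 1, chain="A",
                coords=tuple(pep_xyz[i]), group="peptide",
            )
        )
    for j in range(n_ligand_atoms):
        records.append(
            AtomRecord(
                serial=n_peptide_atoms + j + 1, name=lig_names[j],
                element=lig_elements[j], res_name="LIG", res_seq=1, chain="B",
                coords=tuple(lig_xyz[j]), group="ligand",
            )
        )
    structures = [Structure(tuple(records), model_id=1)]
    return top, frames, structures


# ---------------------------------------------------------------------------
# Fixture bundles

_PRESETS = {
    # n_ligands, n_train, n_replicas, n_frames, dt (ns)
    "paper_like": dict(n_ligands=30, n_train=20, n_replicas=4, n_frames=2001, dt=0.01),
    "minimal": dict(n_ligands=8, n_train=5, n_replicas=1, n_frames=201, dt=0.01),
}


def write_fixture_bundle(out_dir, preset: str = "paper_like", seed: int = 2019) -> dict:
    """Write a self-contained fixture directory and return its manifest.

    ``paper_like`` emulates the full study design: 30 ligands with a 20/10
    train/test split and 4 replicas x 20 ns traces at 10 ps sampling for each
    of the four (component, state) combinations (480 .xvg files).
    ``minimal`` writes 6 ligands, the split tables, one demonstration trace
    and one toy PDB (<= 10 files).  The manifest records the seed, the
    ground-truth parameters, and every written file.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    cfg = _PRESETS[preset]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    gt = GroundTruth(seed=seed)
    dataset = gen_lie_dataset(gt, cfg["n_ligands"])
    train, test = random_split(dataset, cfg["n_train"], seed=seed)

    files: list[str] = []

    def _rel(p: Path) -> str:
        return str(p.relative_to(out_dir))

    for name, subset in (("complexes", dataset), ("train", train), ("test", test)):
        p = out_dir / f"{name}.csv"
        write_complex_table(subset, p)
        files.append(_rel(p))

    trace_entries = []
    trace_seed_rng = np.random.default_rng(seed + 1)
    if preset == "paper_like":
        tdir = out_dir / "traces"
        tdir.mkdir(exist_ok=True)
        for ce, _ in dataset:
            sets = gen_replica_sets(
                ce, gt, cfg["n_replicas"], cfg["n_frames"], cfg["dt"],
                seed=int(trace_seed_rng.integers(2**31)),
            )
            for (comp, state), rs in sets.items():
                for tr in rs.traces:
                    fname = (
                        f"{ce.ligand_id}_{comp.value}_{state.value}_r{tr.replica_id}.xvg"
                    )
                    write_xvg(tr, tdir / fname)
                    files.append(_rel(tdir / fname))
                    trace_entries.append(
                        {
                            "file": _rel(tdir / fname),
                            "ligand_id": ce.ligand_id,
                            "component": comp.value,
                            "state": state.value,
                            "replica_id": tr.replica_id,
                            "true_mean": getattr(
                                ce, f"{comp.value}_{state.value}"
                            ),
                        }
                    )
        for geom in ("contact", "separated", "hbond_ideal"):
            _, _, structs = gen_toy_complex(8, 6, geom, seed=seed)
            p = out_dir / f"toy_{geom}.pdb"
            write_pdb(structs, p)
            files.append(_rel(p))
    else:
        ce0 = dataset[0][0]
        tr = gen_energy_traces(
            ce0.vdw_bound, gt.trace_sd, gt.ar1_phi, cfg["n_frames"], cfg["dt"],
            seed=int(trace_seed_rng.integers(2**31)),
            component=Component.VDW, state=State.BOUND, replica_id=1,
            ligand_id=ce0.ligand_id,
        )
        p = out_dir / "sample_trace.xvg"
        write_xvg(tr, p)
        files.append(_rel(p))
        trace_entries.append(
            {
                "file": _rel(p), "ligand_id": ce0.ligand_id,
                "component": "vdw", "state": "bound", "replica_id": 1,
                "true_mean": ce0.vdw_bound,
            }
        )
        _, _, structs = gen_toy_complex(8, 6, "contact", seed=seed)
        p = out_dir / "toy_contact.pdb"
        write_pdb(structs, p)
        files.append(_rel(p))

    manifest = {
        "preset": preset,
        "seed": seed,
        "ground_truth": {
            "alpha": gt.params.alpha,
            "beta": gt.params.beta,
            "gamma": gt.params.gamma,
            "residual_sd": gt.residual_sd,
            "ar1_phi": gt.ar1_phi,
            "trace_sd": gt.trace_sd,
        },
        "n_ligands": cfg["n_ligands"],
        "n_train": cfg["n_train"],
        "train_ids": [ce.ligand_id for ce, _ in train],
        "test_ids": [ce.ligand_id for ce, _ in test],
        "traces": trace_entries,
        "files": files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    manifest["files"] = files + ["manifest.json"]
    return manifest
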