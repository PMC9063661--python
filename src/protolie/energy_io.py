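"""Reading, cleaning, and averaging interaction-energy time series.

Energy traces come either from GROMACS-style .xvg files (time in ps, energies
in kJ/mol by default) or from plain CSV.  Internally everything is kcal/mol
and nanoseconds.  The standard workflow is: read each replica's trace,
discard the pre-equilibration segment, average within each replica, average
across replicas, and assemble the four (component x state) means into a
ComplexEnergies record for the LIE model.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lie_core import ComplexEnergies

#: Thermochemical calorie: 1 kcal = 4.184 kJ.
KJ_PER_KCAL = 4.184

#: Default equilibration discard (ns): protofibril complexes equilibrate
#: within the first quarter of a 20 ns production run.
DEFAULT_T_EQUIL = 5.0

#: Default number of independent simulation replicas per complex.
DEFAULT_N_REPLICAS = 4


class Component(str, enum.Enum):
    VDW = "vdw"
    ELEC = "elec"


class State(str, enum.Enum):
    BOUND = "bound"
    FREE = "free"


def kj_to_kcal(x):
    return np.asarray(x, dtype=float) / KJ_PER_KCAL


def kcal_to_kj(x):
    return np.asarray(x, dtype=float) * KJ_PER_KCAL


@dataclass(frozen=True)
class EnergyTrace:
    """One component/state/replica ligand–surroundings energy time series.

    times are in ns and strictly increasing; values are in kcal/mol.
    """

    times: np.ndarray
    values: np.ndarray
    component: Component
    state: State
    replica_id: int
    ligand_id: str

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        v = np.atleast_1d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "component", Component(self.component))
        object.__setattr__(self, "state", State(self.state))
        if t.shape != v.shape or t.ndim != 1 or t.size < 1:
            raise ValueError("times and values must be equal-length 1-D, size >= 1")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("times and values must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)


def read_xvg(
    path,
    component: Component | str,
    state: State | str,
    replica_id: int,
    ligand_id: str,
    input_units: str = "kJ_per_mol",
    energy_column: int = 2,
) -> EnergyTrace:
    """Read a GROMACS .xvg energy file into an EnergyTrace.

    Lines starting with '#' or '@' are metadata.  Column 1 is time in ps
    (converted to ns); ``energy_column`` (1-based, default 2) selects the
    energy term.  ``input_units`` is "kJ_per_mol" (GROMACS default, divided
    by 4.184) or "kcal_per_mol".
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(str(path))
    if input_units not in ("kJ_per_mol", "kcal_per_mol"):
        raise ValueError(f"unknown input_units: {input_units!r}")
    if energy_column < 2:
        raise ValueError("energy_column must be >= 2 (column 1 is time)")
    times, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith(("#", "@")):
                continue
            parts = s.split()
            try:
                row = [float(p) for p in parts]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric data line: {s!r}")
            if len(row) < energy_column:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {energy_column} columns, got {len(row)}"
                )
            times.append(row[0])
            values.append(row[energy_column - 1])
    if not times:
        raise ValueError(f"{path}: no data rows")
    t_ns = np.asarray(times) / 1000.0
    v = np.asarray(values)
    if input_units == "kJ_per_mol":
        v = kj_to_kcal(v)
    return EnergyTrace(t_ns, v, component, state, replica_id, ligand_id)


def write_xvg(trace: EnergyTrace, path, output_units: str = "kJ_per_mol") -> None:
    """Write a trace in the .xvg dialect (time in ps), for fixtures and export."""
    if output_units not in ("kJ_per_mol", "kcal_per_mol"):
        raise ValueError(f"unknown output_units: {output_units!r}")
    v = trace.values if output_units == "kcal_per_mol" else kcal_to_kj(trace.values)
    header = (
        f"# protolie energy trace ligand={trace.ligand_id} "
        f"component={trace.component.value} state={trace.state.value} "
        f"replica={trace.replica_id}\n"
        '@    title "Interaction energy"\n'
        '@    xaxis  label "Time (ps)"\n'
        f'@    yaxis  label "Energy ({output_units})"\n'
    )
    body = np.column_stack([trace.times * 1000.0, v])
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.12g")


def read_trace_csv(
    path, component, state, replica_id: int, ligand_id: str
) -> EnergyTrace:
    """Read a CSV trace with header ``time_ns,energy_kcal_mol``."""
    df = pd.read_csv(path)
    if not {"time_ns", "energy_kcal_mol"}.issubset(df.columns):
        raise ValueError(f"{path}: need columns time_ns,energy_kcal_mol")
    return EnergyTrace(
        df["time_ns"].to_numpy(),
        df["energy_kcal_mol"].to_numpy(),
        component,
        state,
        replica_id,
        ligand_id,
    )


def write_trace_csv(trace: EnergyTrace, path) -> None:
    pd.DataFrame(
        {"time_ns": trace.times, "energy_kcal_mol": trace.values}
    ).to_csv(path, index=False, float_format="%.8g")


def discard_equilibration(trace: EnergyTrace, t_equil: float = DEFAULT_T_EQUIL) -> EnergyTrace:
    """Drop all frames with time <= t_equil (ns); metadata is preserved.

    The frame at exactly t_equil is discarded (strict inequality).
    """
    if t_equil < 0:
        raise ValueError("t_equil must be >= 0")
    mask = trace.times > t_equil
    if not mask.any():
        raise ValueError(
            f"no frames after t_equil={t_equil} ns (trace ends at "
            f"{trace.times[-1]} ns)"
        )
    return EnergyTrace(
        trace.times[mask],
        trace.values[mask],
        trace.component,
        trace.state,
        trace.replica_id,
        trace.ligand_id,
    )


def trace_mean(trace: EnergyTrace) -> float:
    """Arithmetic mean energy (kcal/mol) of a trace."""
    return float(np.mean(trace.values))


@dataclass(frozen=True)
class ReplicaSet:
    """Replicated traces of one (ligand, component, state) combination."""

    traces: tuple[EnergyTrace, ...]
    expected_replicas: int = DEFAULT_N_REPLICAS

    def __post_init__(self) -> None:
        traces = tuple(self.traces)
        object.__setattr__(self, "traces", traces)
        if not traces:
            raise ValueError("ReplicaSet needs at least one trace")
        first = traces[0]
        for t in traces[1:]:
            if (
                t.ligand_id != first.ligand_id
                or t.component != first.component
                or t.state != first.state
            ):
                raise ValueError(
                    "all traces in a ReplicaSet must share ligand_id, "
                    "component, and state"
                )

    @property
    def ligand_id(self) -> str:
        return self.traces[0].ligand_id

    @property
    def component(self) -> Component:
        return self.traces[0].component

    @property
    def state(self) -> State:
        return self.traces[0].state


def replica_average(rs: ReplicaSet, t_equil: float = DEFAULT_T_EQUIL) -> float:
    """Unweighted mean of per-replica post-equilibration means (kcal/mol).

    Warns (without failing) when the replica count differs from
    ``rs.expected_replicas``.  For equal-length replicas this equals the
    frame-pooled mean.
    """
    if len(rs.traces) != rs.expected_replicas:
        warnings.warn(
            f"{rs.ligand_id} {rs.component.value}/{rs.state.value}: "
            f"{len(rs.traces)} replicas (expected {rs.expected_replicas})",
            stacklevel=2,
        )
    means = [trace_mean(discard_equilibration(t, t_equil)) for t in rs.traces]
    return float(np.mean(means))


def assemble_complex_energies(
    bound_vdw: ReplicaSet,
    bound_elec: ReplicaSet,
    free_vdw: ReplicaSet,
    free_elec: ReplicaSet,
    t_equil: float = DEFAULT_T_EQUIL,
) -> ComplexEnergies:
    """Package the four replica-averaged energies into one ComplexEnergies."""
    sets = {
        (Component.VDW, State.BOUND): bound_vdw,
        (Component.ELEC, State.BOUND): bound_elec,
        (Component.VDW, State.FREE): free_vdw,
        (Component.ELEC, State.FREE): free_elec,
    }
    ligand_ids = {rs.ligand_id for rs in sets.values()}
    if len(ligand_ids) != 1:
        raise ValueError(f"ligand_id mismatch across replica sets: {sorted(ligand_ids)}")
    for (comp, state), rs in sets.items():
        if rs.component != comp or rs.state != state:
            raise ValueError(
                f"replica set passed as {comp.value}/{state.value} is labelled "
                f"{rs.component.value}/{rs.state.value}"
            )
    return ComplexEnergies(
        ligand_id=ligand_ids.pop(),
        vdw_bound=replica_average(bound_vdw, t_equil),
        vdw_free=replica_average(free_vdw, t_equil),
        elec_bound=replica_average(bound_elec, t_equil),
        elec_free=replica_average(free_elec, t_equil),
    )


# ---------------------------------------------------------------------------
# Per-ligand complex tables (the transcribed-table CSV layout)

_TABLE_COLUMNS = ["ligand_id", "vdw_bound", "vdw_free", "elec_bound", "elec_free"]


def read_complex_table(path):
    """Read a per-ligand table CSV into (ComplexEnergies, AffinityRecord|None) pairs.

    Header: ``ligand_id,vdw_bound,vdw_free,elec_bound,elec_free,dg_exp``
    (kcal/mol); the dg_exp column is optional (prediction-only tables).
    """
    from .lie_core import AffinityRecord

    df = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_dg = "dg_exp" in df.columns
    out = []
    for row in df.itertuples(index=False):
        ce = ComplexEnergies(
            ligand_id=str(row.ligand_id),
            vdw_bound=float(row.vdw_bound),
            vdw_free=float(row.vdw_free),
            elec_bound=float(row.elec_bound),
            elec_free=float(row.elec_free),
        )
        aff = (
            AffinityRecord(ligand_id=str(row.ligand_id), dg_exp=float(row.dg_exp))
            if has_dg
            else None
        )
        out.append((ce, aff))
    if not out:
        raise ValueError(f"{path}: empty table")
    return out


def write_complex_table(dataset, path) -> None:
    """Write (ComplexEnergies, AffinityRecord|None) pairs as a table CSV."""
    rows = []
    for ce, aff in dataset:
        row = {
            "ligand_id": ce.ligand_id,
            "vdw_bound": ce.vdw_bound,
            "vdw_free": ce.vdw_free,
            "elec_bound": ce.elec_bound,
            "elec_free": ce.elec_free,
        }
        if aff is not None:
            row["dg_exp"] = aff.dg
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
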