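"""Structural analyses: Calpha RMSD, hydrogen bonds, hydrophobic contacts.

Implements the three trajectory analyses used to characterise protofibril–
ligand complexes:

* Calpha RMSD of the peptides versus the initial configuration, after
  optimal (Kabsch) rigid superposition;
* geometric hydrogen bonds across the ligand–peptide interface:
  donor–acceptor distance < 3.5 A and A–H–D angle > 135 degrees;
* non-bonded (hydrophobic) contacts: any ligand C or S atom within
  2.9–3.9 A (closed interval) of any peptide atom.

PDB input/output is handled by biotite; a multi-model file is treated as a
trajectory with the frame index standing in for time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation

#: Geometric hydrogen-bond gates (strict inequalities).
HB_MAX_DA_DISTANCE = 3.5  # A, donor–acceptor
HB_MIN_ANGLE = 135.0  # degrees, acceptor–hydrogen–donor

#: Non-bonded-contact distance window (closed interval), A.
NBC_MIN = 2.9
NBC_MAX = 3.9

#: Maximum H–donor covalent assignment distance, A.
H_BOND_ASSIGN = 1.2

_WATER_RES = {"HOH", "WAT", "SOL", "TIP", "TIP3", "TIP4", "SPC"}
_ION_RES = {"NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "BR", "IOD", "CS", "LI"}

_DONOR_ELEMENTS = {"N", "O", "S"}
_ACCEPTOR_ELEMENTS = {"N", "O"}


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    coords: tuple[float, float, float]
    group: str  # "peptide" | "ligand" | "other"

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if self.group not in ("peptide", "ligand", "other"):
            raise ValueError(f"atom {self.serial}: unknown group {self.group!r}")


@dataclass(frozen=True)
class Structure:
    """An ordered set of atoms from one model of a PDB file."""

    atoms: tuple[AtomRecord, ...]
    model_id: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if not self.atoms:
            raise ValueError("Structure needs at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials within a model")

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def indices(self, group: str) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.group == group]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """A copy with coordinates mapped through x -> R x + t."""
        new_coords = self.coords() @ np.asarray(rotation).T + np.asarray(translation)
        atoms = tuple(
            AtomRecord(
                a.serial, a.name, a.element, a.res_name, a.res_seq, a.chain,
                tuple(c), a.group,
            )
            for a, c in zip(self.atoms, new_coords)
        )
        return Structure(atoms, self.model_id)


def _classify(hetero: bool, res_name: str) -> str:
    if not hetero:
        return "peptide"
    if res_name.strip().upper() in _WATER_RES | _ION_RES:
        return "other"
    return "ligand"


def read_pdb(path) -> list[Structure]:
    """Read a (possibly multi-MODEL) PDB file into one Structure per model.

    Protein ATOM records are classified as group "peptide", non-water/ion
    HETATM records as "ligand", waters and counter-ions as "other".  Only
    the first alternate location of each atom is kept.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no models")
    structures = []
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m, altloc="first", extra_fields=["atom_id"])
        if arr.array_length() == 0:
            raise ValueError(f"{path}: model {m} has no atoms")
        atoms = []
        for i in range(arr.array_length()):
            res_name = str(arr.res_name[i])
            atoms.append(
                AtomRecord(
                    serial=int(arr.atom_id[i]),
                    name=str(arr.atom_name[i]),
                    element=str(arr.element[i]).upper(),
                    res_name=res_name,
                    res_seq=int(arr.res_id[i]),
                    chain=str(arr.chain_id[i]),
                    coords=tuple(float(c) for c in arr.coord[i]),
                    group=_classify(bool(arr.hetero[i]), res_name),
                )
            )
        structures.append(Structure(tuple(atoms), model_id=m))
    return structures


def write_pdb(structures: Sequence[Structure], path) -> None:
    """Write Structures as a (multi-MODEL) PDB file; all models must share atoms."""
    structures = list(structures)
    if not structures:
        raise ValueError("need at least one structure")
    arrays = []
    for s in structures:
        n = len(s.atoms)
        arr = struc.AtomArray(n)
        arr.coord = s.coords()
        arr.chain_id = np.array([a.chain for a in s.atoms])
        arr.res_id = np.array([a.res_seq for a in s.atoms])
        arr.res_name = np.array([a.res_name for a in s.atoms])
        arr.atom_name = np.array([a.name for a in s.atoms])
        arr.element = np.array([a.element for a in s.atoms])
        arr.hetero = np.array([a.group != "peptide" for a in s.atoms])
        arr.set_annotation("atom_id", np.array([a.serial for a in s.atoms]))
        arrays.append(arr)
    pdb = PDBFile()
    pdb.set_structure(arrays[0] if len(arrays) == 1 else struc.stack(arrays))
    pdb.write(str(path))


def relabel_ligand(s: Structure, res_name: str) -> Structure:
    """Force atoms of one residue name into the ligand group (others by record type)."""
    atoms = tuple(
        AtomRecord(
            a.serial, a.name, a.element, a.res_name, a.res_seq, a.chain, a.coords,
            "ligand" if a.res_name.strip() == res_name else
            (a.group if a.group != "ligand" else "other"),
        )
        for a in s.atoms
    )
    return Structure(atoms, s.model_id)


# ---------------------------------------------------------------------------
# Superposition and RMSD

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that R @ x + t best matches
    the reference in the least-squares sense; the rotation is proper
    (det = +1).  Requires >= 3 non-collinear reference points.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    if mob.shape[0] < 3:
        raise ValueError("need at least 3 points")
    mc = mob.mean(axis=0)
    rc = ref.mean(axis=0)
    ref_c = ref - rc
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) reference geometry")
    rot, _ = Rotation.align_vectors(ref_c, mob - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    aligned = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - ref) ** 2, axis=1))))
    return R, t, rmsd


def _ca_coords(s: Structure) -> tuple[list, np.ndarray]:
    keyed = [
        ((a.chain, a.res_seq, a.name), a.coords)
        for a in s.atoms
        if a.group == "peptide" and a.name.strip() == "CA"
    ]
    keyed.sort(key=lambda kv: kv[0])
    keys = [k for k, _ in keyed]
    return keys, np.array([c for _, c in keyed], dtype=float)


def ca_rmsd_series(
    frames: Sequence[Structure], reference_model: int = 0
) -> list[tuple[int, float]]:
    """Kabsch-aligned Calpha RMSD of each frame against a reference frame.

    ``reference_model`` indexes into ``frames`` (default: the first frame,
    i.e. the initial configuration).  Every frame must contain the same set
    of peptide CA atoms.  Returns (frame_index, rmsd_A) pairs.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    ref_keys, ref = _ca_coords(frames[reference_model])
    if len(ref_keys) < 3:
        raise ValueError("reference frame has fewer than 3 peptide CA atoms")
    out = []
    for i, s in enumerate(frames):
        keys, xyz = _ca_coords(s)
        if keys != ref_keys:
            raise ValueError(f"frame {i}: CA atom set differs from reference")
        _, _, rmsd = kabsch_superpose(xyz, ref)
        out.append((i, rmsd))
    return out


# ---------------------------------------------------------------------------
# Hydrogen bonds and non-bonded contacts

@dataclass(frozen=True)
class HBond:
    """One interface hydrogen bond (indices into Structure.atoms)."""

    donor_idx: int
    h_idx: int
    acceptor_idx: int
    distance: float  # A, donor–acceptor
    angle: float  # degrees, acceptor–hydrogen–donor

    def __post_init__(self) -> None:
        if not self.distance < HB_MAX_DA_DISTANCE:
            raise ValueError("hydrogen bond distance gate violated")
        if not self.angle > HB_MIN_ANGLE:
            raise ValueError("hydrogen bond angle gate violated")


def detect_hbonds(s: Structure) -> list[HBond]:
    """Geometric hydrogen bonds across the ligand–peptide interface.

    A hydrogen is assigned to the nearest N/O/S heavy atom within 1.2 A;
    heavy atoms with at least one assigned hydrogen are donors, N/O atoms
    are acceptors.  Both donor directions (ligand->peptide and
    peptide->ligand) are scanned; intra-molecule pairs and waters/ions are
    excluded.  Raises if the structure carries no hydrogens, since the
    criterion cannot be evaluated without them.
    """
    coords = s.coords()
    elements = np.array([a.element for a in s.atoms])
    groups = np.array([a.group for a in s.atoms])
    relevant = (groups == "ligand") | (groups == "peptide")

    h_idx = np.where((elements == "H") & relevant)[0]
    if h_idx.size == 0:
        raise ValueError(
            "structure contains no hydrogens: the geometric hydrogen-bond "
            "criterion requires explicit hydrogens"
        )
    donor_capable = np.where(np.isin(elements, list(_DONOR_ELEMENTS)) & relevant)[0]
    acceptors = np.where(np.isin(elements, list(_ACCEPTOR_ELEMENTS)) & relevant)[0]

    donor_hydrogens: dict[int, list[int]] = {}
    for h in h_idx:
        if donor_capable.size == 0:
            break
        d2 = np.sum((coords[donor_capable] - coords[h]) ** 2, axis=1)
        k = int(np.argmin(d2))
        if d2[k] <= H_BOND_ASSIGN**2:
            donor_hydrogens.setdefault(int(donor_capable[k]), []).append(int(h))

    bonds = []
    for donor, hydrogens in sorted(donor_hydrogens.items()):
        dg = groups[donor]
        for acc in acceptors:
            if acc == donor or groups[acc] == dg:
                continue
            dist = float(np.linalg.norm(coords[donor] - coords[acc]))
            if not dist < HB_MAX_DA_DISTANCE:
                continue
            for h in hydrogens:
                v1 = coords[donor] - coords[h]
                v2 = coords[acc] - coords[h]
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom == 0:
                    continue
                cosang = np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)
                angle = float(np.degrees(np.arccos(cosang)))
                if angle > HB_MIN_ANGLE:
                    bonds.append(HBond(donor, h, int(acc), dist, angle))
    return bonds


@dataclass(frozen=True)
class Contact:
    ligand_idx: int
    peptide_idx: int
    distance: float  # A


def count_nbc(s: Structure) -> tuple[int, list[Contact]]:
    """Hydrophobic non-bonded contacts: ligand C/S within [2.9, 3.9] A of any peptide atom.

    Each qualifying (ligand atom, peptide atom) pair counts once; the
    distance window is a closed interval.  Returns (count, per-pair list).
    """
    lig = [
        i for i, a in enumerate(s.atoms)
        if a.group == "ligand" and a.element in ("C", "S")
    ]
    pep = s.indices("peptide")
    if not s.indices("ligand"):
        raise ValueError("structure has no ligand atoms")
    coords = s.coords()
    contacts = []
    for i in lig:
        d = np.linalg.norm(coords[pep] - coords[i], axis=1)
        for j, dist in zip(pep, d):
            if NBC_MIN <= dist <= NBC_MAX:
                contacts.append(Contact(i, int(j), float(dist)))
    return len(contacts), contacts


def hbond_replica_average(replicas: Sequence[Sequence[float]]) -> float:
    """Mean hydrogen-bond count: per-frame mean within each replica, then
    unweighted mean across replicas."""
    replicas = [list(r) for r in replicas]
    if not replicas or any(len(r) == 0 for r in replicas):
        raise ValueError("each replica needs at least one frame count")
    return float(np.mean([np.mean(r) for r in replicas]))
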