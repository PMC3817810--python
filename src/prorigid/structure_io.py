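"""Molecular structures: PDB input/output and deterministic fixture builders.

Atoms are stored in input order with their PDB identity (chain, residue
number, insertion code, atom name).  Curation on input keeps a single
alternate location per atom site (highest occupancy, ties broken by file
order), always drops waters, and keeps HETATM records only on request.

Only backbone amide hydrogens are ever placed by this package; side-chain
polar hydrogens must already be present in the input for side-chain hydrogen
bonds to be detected (a documented limitation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "MolecularStructure",
    "read_pdb",
    "write_pdb",
    "build_ethane",
    "build_ideal_helix",
    "place_backbone_amide_hydrogens",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class EmptyStructureError(ValueError):
    """Raised when curation leaves no atoms."""


@dataclass(frozen=True)
class Atom:
    """A single atom with PDB-style identity and Cartesian coordinates (Å)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    insertion_code: str = ""
    alt_loc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValueError(f"atom {self.name}: element symbol required")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain_id, residue_number, insertion_code) identity of the residue."""
        return (self.chain_id, self.residue_number, self.insertion_code)

    def distance_to(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.position - other.position))


@dataclass
class MolecularStructure:
    """An ordered collection of curated atoms."""

    atoms: list[Atom]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError(f"{self.source_id or 'structure'}: no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def residues(self) -> list[tuple[str, int, str]]:
        """Residue keys in order of first appearance."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def atoms_by_residue(self) -> dict[tuple[str, int, str], list[Atom]]:
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out


# ---------------------------------------------------------------------------
# PDB I/O (reading backed by gemmi)
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, keep_het: bool = False) -> MolecularStructure:
    """Read and curate a PDB file.

    Curation: highest-occupancy alternate location kept per atom site (ties:
    first listed); waters always dropped; HETATM records kept only when
    ``keep_het`` is set.

    Raises
    ------
    OSError
        If the file cannot be read.
    EmptyStructureError
        If no atoms survive curation.
    """
    st = gemmi.read_pdb(str(path))
    atoms: list[Atom] = []
    serial = 0
    for model in st:
        for chain in model:
            for res in chain:
                if res.name in _WATER_NAMES or res.is_water():
                    continue
                het = res.het_flag == "H"
                if het and not keep_het:
                    continue
                # resolve alternate locations per atom name
                by_name: dict[str, gemmi.Atom] = {}
                for at in res:
                    prev = by_name.get(at.name)
                    if prev is None or at.occ > prev.occ:
                        by_name[at.name] = at
                for at in by_name.values():
                    serial += 1
                    atoms.append(
                        Atom(
                            serial=serial,
                            name=at.name,
                            element=at.element.name or at.name[0],
                            residue_name=res.name,
                            residue_number=res.seqid.num,
                            chain_id=chain.name or "A",
                            insertion_code=(res.seqid.icode or "").strip(),
                            position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            alt_loc=(at.altloc or "").strip(),
                            is_hetero=het,
                        )
                    )
        break  # first model only
    if not atoms:
        raise EmptyStructureError(f"{path}: no atoms after curation")
    return MolecularStructure(atoms=atoms, source_id=Path(path).stem)


def write_pdb(structure: MolecularStructure, path: str | Path) -> None:
    """Write fixed-column (v3.3) ATOM/HETATM records.

    Coordinates are written with 3 decimals, so a read/write round trip
    preserves positions to 0.001 Å.
    """
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        record = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        x, y, z = a.position
        lines.append(
            f"{record}{i:5d} {name}{a.alt_loc or ' '}{a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.residue_number:4d}{a.insertion_code or ' '}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Position a fourth atom D given chain A-B-C, |C-D|, angle B-C-D and
    torsion A-B-C-D (natural extension reference frame)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return math.degrees(math.atan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


# ---------------------------------------------------------------------------
# Fixture builders (seedless, bit-stable)
# ---------------------------------------------------------------------------

_CC = 1.54      # Å, sp3 C-C
_CH = 1.09      # Å, C-H
_TET = 109.4712206344907  # tetrahedral angle, degrees


def build_ethane() -> MolecularStructure:
    """Staggered ethane, C-C 1.54 Å, C-H 1.09 Å, tetrahedral angles."""
    c1 = np.zeros(3)
    c2 = np.array([_CC, 0.0, 0.0])
    atoms = [
        Atom(1, "C1", "C", "ETH", 1, "A", c1, is_hetero=True),
        Atom(2, "C2", "C", "ETH", 1, "A", c2, is_hetero=True),
    ]
    # hydrogens on C1 (reference frame uses a dummy atom off-axis)
    dummy = np.array([_CC, 1.0, 0.0])
    serial = 3
    for tor in (0.0, 120.0, 240.0):
        pos = _place_atom(dummy, c2, c1, _CH, _TET, tor)
        atoms.append(Atom(serial, f"H{serial - 2}", "H", "ETH", 1, "A", pos, is_hetero=True))
        serial += 1
    for tor in (60.0, 180.0, 300.0):  # staggered w.r.t. the C1 hydrogens
        pos = _place_atom(dummy - np.array([_CC, 0, 0]), c1, c2, _CH, _TET, tor)
        atoms.append(Atom(serial, f"H{serial - 2}", "H", "ETH", 1, "A", pos, is_hetero=True))
        serial += 1
    return MolecularStructure(atoms=atoms, source_id="ethane")


# Backbone internal coordinates (Engh-Huber-style standard values, Å / deg).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.0, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


def build_ideal_helix(n_res: int, phi: float = -57.0, psi: float = -47.0,
                      omega: float = 180.0) -> MolecularStructure:
    """Ideal polyalanine α-helix backbone (N, H, CA, C, O, CB per residue).

    Residues are numbered 1..n_res on chain A.  The first residue carries no
    amide hydrogen (its preceding peptide plane does not exist), so it has 5
    atoms while every later residue has 6.
    """
    if n_res < 2:
        raise ValueError("build_ideal_helix requires n_res >= 2")
    # seed residue 1 in the xy-plane
    n = [np.zeros(3)]
    ca = [np.array([_B_N_CA, 0.0, 0.0])]
    c = [_place_atom(np.array([0.0, 1.0, 0.0]), n[0], ca[0], _B_CA_C, _A_N_CA_C, 0.0)]
    for i in range(1, n_res):
        n.append(_place_atom(n[i - 1], ca[i - 1], c[i - 1], _B_C_N, _A_CA_C_N, psi))
        ca.append(_place_atom(ca[i - 1], c[i - 1], n[i], _B_N_CA, _A_C_N_CA, omega))
        c.append(_place_atom(c[i - 1], n[i], ca[i], _B_CA_C, _A_N_CA_C, phi))

    atoms: list[Atom] = []
    serial = 0

    def add(name: str, element: str, res: int, pos: np.ndarray) -> None:
        nonlocal serial
        serial += 1
        atoms.append(Atom(serial, name, element, "ALA", res, "A", pos))

    for i in range(n_res):
        res = i + 1
        add("N", "N", res, n[i])
        if i > 0:
            # amide H in the peptide plane, bisecting opposite C(prev)-N-CA
            u = c[i - 1] - n[i]
            v = ca[i] - n[i]
            h_dir = -(u / np.linalg.norm(u) + v / np.linalg.norm(v))
            h_dir /= np.linalg.norm(h_dir)
            add("H", "H", res, n[i] + _B_N_H * h_dir)
        add("CA", "C", res, ca[i])
        add("C", "C", res, c[i])
        # carbonyl O in the peptide plane, trans to the next N
        add("O", "O", res, _place_atom(n[i], ca[i], c[i], _B_C_O, _A_CA_C_O, psi + 180.0))
        # CB: tetrahedral off CA, L-chirality
        n1 = (n[i] - ca[i]) / np.linalg.norm(n[i] - ca[i])
        n2 = (c[i] - ca[i]) / np.linalg.norm(c[i] - ca[i])
        bisector = -(n1 + n2)
        bisector /= np.linalg.norm(bisector)
        perp = np.cross(n1, n2)
        perp /= np.linalg.norm(perp)
        half = math.radians(_A_N_CA_C / 2.0)
        a_coef = (1.0 / 3.0) / math.cos(half)
        b_coef = math.sqrt(max(0.0, 1.0 - a_coef * a_coef))
        cb_dir = a_coef * bisector + b_coef * perp
        add("CB", "C", res, ca[i] + _B_CA_CB * cb_dir / np.linalg.norm(cb_dir))
    return MolecularStructure(atoms=atoms, source_id=f"helix{n_res}")


def place_backbone_amide_hydrogens(structure: MolecularStructure) -> MolecularStructure:
    """Add missing backbone amide hydrogens.

    For every non-proline residue whose backbone N has no bonded hydrogen and
    whose geometry (previous residue's C, own N and CA) is available, an H is
    placed at 1.0 Å along the in-plane bisector opposite the C(prev)-N-CA
    directions.  Residues with missing geometry are skipped.  Existing
    hydrogens are never moved, so the operation is idempotent.
    """
    by_res = structure.atoms_by_residue()
    res_keys = structure.residues()
    new_atoms = list(structure.atoms)
    serial = max(a.serial for a in structure.atoms)
    for idx, key in enumerate(res_keys):
        res_atoms = {a.name: a for a in by_res[key]}
        if res_atoms.get("N") is None or "CA" not in res_atoms:
            continue
        if by_res[key][0].residue_name == "PRO":
            continue
        n_atom = res_atoms["N"]
        has_h = any(
            a.element == "H" and a.distance_to(n_atom) < 1.3 for a in by_res[key]
        )
        if has_h:
            continue
        if idx == 0:
            continue  # N-terminus: no preceding carbonyl
        prev_key = res_keys[idx - 1]
        prev = {a.name: a for a in by_res[prev_key]}
        if "C" not in prev or prev_key[0] != key[0]:
            continue
        if prev["C"].distance_to(n_atom) > 2.0:
            continue  # chain break
        u = prev["C"].position - n_atom.position
        v = res_atoms["CA"].position - n_atom.position
        h_dir = -(u / np.linalg.norm(u) + v / np.linalg.norm(v))
        h_dir /= np.linalg.norm(h_dir)
        serial += 1
        new_atoms.append(
            Atom(
                serial, "H", "H", n_atom.residue_name, n_atom.residue_number,
                n_atom.chain_id, n_atom.position + _B_N_H * h_dir,
                insertion_code=n_atom.insertion_code, is_hetero=n_atom.is_hetero,
            )
        )
    return MolecularStructure(atoms=new_atoms, source_id=structure.source_id)
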