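"""Detection and energy scoring of covalent and noncovalent interactions.

Hydrogen bonds are detected with HBPLUS-like geometric defaults (donor-
acceptor distance <= 3.9 Å, hydrogen-acceptor distance <= 2.5 Å, D-H-A angle
>= 90°) and scored with the Mayo-lab closed-form energy function:

    E = V0 * [5 (d0/d)^12 - 6 (d0/d)^10] * F(theta, phi, gamma)

with V0 = 8 kcal/mol, d0 = 2.8 Å and d the donor-acceptor distance.  The
angular factor F depends on the donor/acceptor hybridization (see
``mayo_energy``).

Hydrophobic interactions come in two flavours: the legacy van-der-Waals
surface heuristic (C/S pairs within 0.25 Å of vdW contact, no energies) and
the Lennard-Jones 6-12 method, which scores every heavy-atom pair within a
distance cap using per-element Amber-99-style well depths combined with
Lorentz-Berthelot mixing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from prorigid.structure_io import Atom, MolecularStructure, angle_deg

__all__ = [
    "CovalentBond",
    "HBondCriteria",
    "HydrogenBond",
    "HydrophobicInteraction",
    "ConfigurationCensus",
    "infer_covalent_bonds",
    "detect_hbonds",
    "mayo_energy",
    "classify_hbond_configurations",
    "detect_hydrophobics_legacy",
    "detect_hydrophobics_lj",
    "lj_energy",
    "filter_by_energy",
]

# Covalent radii (Å, Cordero et al. 2008) for the elements that occur in
# protein + common-ligand structures.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
}
_BOND_TOLERANCE = 0.45  # Å added to the radii sum

# van der Waals radii (Å, Bondi) used by the legacy hydrophobic heuristic.
VDW_RADII = {"C": 1.70, "S": 1.80}
_LEGACY_SURFACE_CUTOFF = 0.25  # Å between vdW surfaces

# Per-element Lennard-Jones parameters in the Amber-99 style:
# (well depth epsilon in kcal/mol, Rmin/2 in Å).  sigma = 2 * Rmin/2 * 2^(-1/6).
_LJ_PARAMS = {
    "C": (0.1094, 1.9080),
    "N": (0.1700, 1.8240),
    "O": (0.2100, 1.6612),
    "S": (0.2500, 2.0000),
}
_SIGMA_FACTOR = 2.0 ** (-1.0 / 6.0) * 2.0

# Mayo energy function constants.
MAYO_V0 = 8.0   # kcal/mol
MAYO_D0 = 2.8   # Å

NO_ENERGY = math.nan  # sentinel for legacy hydrophobics


@dataclass(frozen=True)
class CovalentBond:
    atom_a: Atom
    atom_b: Atom
    rotatable: bool = True
    kind: str = "single"  # single | peptide | double | disulfide | ring

    def __post_init__(self) -> None:
        if self.atom_a is self.atom_b:
            raise ValueError("covalent bond requires two distinct atoms")
        if self.kind in ("peptide", "double", "ring") and self.rotatable:
            raise ValueError(f"{self.kind} bonds are non-rotatable")

    @property
    def key(self) -> frozenset[int]:
        return frozenset((self.atom_a.serial, self.atom_b.serial))


@dataclass
class HydrogenBond:
    donor: Atom
    hydrogen: Atom
    acceptor: Atom
    acceptor_bases: list[Atom]
    d_HA: float
    d_DA: float
    theta: float        # D-H-A angle, degrees
    phi: float          # H-A-AB angle, degrees
    gamma: float        # in-plane angle for sp2 acceptors, degrees
    donor_hybrid: str   # sp2 | sp3
    acceptor_hybrid: str
    energy: float = 0.0  # kcal/mol
    configuration: str = ""


@dataclass
class HydrophobicInteraction:
    atom_a: Atom
    atom_b: Atom
    r: float
    epsilon: float = NO_ENERGY
    sigma: float = NO_ENERGY
    energy: float = NO_ENERGY
    source: str = "lennard_jones"  # lennard_jones | legacy


@dataclass
class HBondCriteria:
    """Geometric acceptance thresholds for hydrogen bond detection."""

    d_DA_max: float = 3.9
    d_HA_max: float = 2.5
    theta_min: float = 90.0

    def validate(self) -> None:
        if self.d_DA_max <= 0 or self.d_HA_max <= 0:
            raise ValueError("distance criteria must be positive")


@dataclass
class ConfigurationCensus:
    """Per-bond configuration labels plus aggregate counts and fractions."""

    total: int
    labels: list[set[str]]
    counts: dict[str, int]
    fractions: dict[str, float]


# ---------------------------------------------------------------------------
# Covalent bonds
# ---------------------------------------------------------------------------

# Side-chain bonds that are planar (sp2 / aromatic / resonant) and therefore
# non-rotatable, keyed by residue name.  Pairs are atom-name frozensets.
_RING = "ring"
_DOUBLE = "double"
_NONROT_TEMPLATES: dict[str, dict[frozenset[str], str]] = {
    "ARG": {frozenset(p): _DOUBLE for p in
            [("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")]},
    "ASP": {frozenset(p): _DOUBLE for p in [("CG", "OD1"), ("CG", "OD2")]},
    "GLU": {frozenset(p): _DOUBLE for p in [("CD", "OE1"), ("CD", "OE2")]},
    "ASN": {frozenset(p): _DOUBLE for p in [("CG", "OD1"), ("CG", "ND2")]},
    "GLN": {frozenset(p): _DOUBLE for p in [("CD", "OE1"), ("CD", "NE2")]},
    "PHE": {frozenset(p): _RING for p in
            [("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"), ("CD2", "CE2"),
             ("CE1", "CZ"), ("CE2", "CZ")]},
    "TYR": {frozenset(p): _RING for p in
            [("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"), ("CD2", "CE2"),
             ("CE1", "CZ"), ("CE2", "CZ")]},
    "HIS": {frozenset(p): _RING for p in
            [("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"), ("CD2", "NE2"),
             ("CE1", "NE2")]},
    "TRP": {frozenset(p): _RING for p in
            [("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"), ("NE1", "CE2"),
             ("CD2", "CE2"), ("CD2", "CE3"), ("CE2", "CZ2"), ("CE3", "CZ3"),
             ("CZ2", "CH2"), ("CZ3", "CH2")]},
    "PRO": {frozenset(p): _RING for p in
            [("N", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD"),
             ("CD", "N")]},
}


def infer_covalent_bonds(structure: MolecularStructure) -> list[CovalentBond]:
    """Infer covalent connectivity from inter-atomic distances.

    Two atoms are bonded when their distance does not exceed the sum of their
    covalent radii plus 0.45 Å (H-H pairs never bond).  S-S pairs within
    2.3 Å are flagged as disulfides; inter-residue C-N bonds between
    consecutive residues as (non-rotatable) peptide bonds; backbone carbonyl
    C=O and templated side-chain sp2/ring bonds as non-rotatable.
    """
    atoms = structure.atoms
    coords = structure.coords
    tree = cKDTree(coords)
    max_cut = max(COVALENT_RADII.values()) * 2 + _BOND_TOLERANCE
    bonds: list[CovalentBond] = []
    for i, j in sorted(tree.query_pairs(max_cut)):
        a, b = atoms[i], atoms[j]
        ea, eb = a.element.upper(), b.element.upper()
        if ea == "H" and eb == "H":
            continue
        ra = COVALENT_RADII.get(ea)
        rb = COVALENT_RADII.get(eb)
        if ra is None or rb is None:
            continue
        d = a.distance_to(b)
        if d > ra + rb + _BOND_TOLERANCE:
            continue
        kind, rotatable = "single", True
        if {ea, eb} == {"S"}:
            if d > 2.3:
                continue
            kind, rotatable = "disulfide", True
        elif {a.name, b.name} == {"C", "N"} and a.residue_key != b.residue_key:
            kind, rotatable = "peptide", False
        elif {a.name, b.name} == {"C", "O"} and a.residue_key == b.residue_key:
            kind, rotatable = "double", False  # backbone carbonyl
        elif a.residue_key == b.residue_key:
            tmpl = _NONROT_TEMPLATES.get(a.residue_name, {})
            k = tmpl.get(frozenset((a.name, b.name)))
            if k is not None:
                kind, rotatable = k, False
        bonds.append(CovalentBond(a, b, rotatable=rotatable, kind=kind))
    return bonds


def _bond_graph(structure: MolecularStructure,
                bonds: list[CovalentBond]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(a.serial for a in structure.atoms)
    g.add_edges_from((b.atom_a.serial, b.atom_b.serial) for b in bonds)
    return g


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

# Hybridization templates: (residue, atom name) -> sp2/sp3, with element
# fallbacks below.  Backbone N and O are sp2 (amide resonance).
_HYBRID_TEMPLATES = {
    ("*", "N"): "sp2", ("*", "O"): "sp2", ("*", "OXT"): "sp2",
    ("SER", "OG"): "sp3", ("THR", "OG1"): "sp3", ("TYR", "OH"): "sp2",
    ("ASP", "OD1"): "sp2", ("ASP", "OD2"): "sp2",
    ("GLU", "OE1"): "sp2", ("GLU", "OE2"): "sp2",
    ("ASN", "OD1"): "sp2", ("ASN", "ND2"): "sp2",
    ("GLN", "OE1"): "sp2", ("GLN", "NE2"): "sp2",
    ("HIS", "ND1"): "sp2", ("HIS", "NE2"): "sp2",
    ("ARG", "NE"): "sp2", ("ARG", "NH1"): "sp2", ("ARG", "NH2"): "sp2",
    ("LYS", "NZ"): "sp3", ("TRP", "NE1"): "sp2",
    ("CYS", "SG"): "sp3", ("MET", "SD"): "sp3",
}
_HYBRID_FALLBACK = {"N": "sp2", "O": "sp3", "S": "sp3"}


def _hybridization(atom: Atom) -> str:
    for key in ((atom.residue_name, atom.name), ("*", atom.name)):
        if key in _HYBRID_TEMPLATES:
            return _HYBRID_TEMPLATES[key]
    return _HYBRID_FALLBACK.get(atom.element.upper(), "sp3")


def _sp2_plane_gamma(hydrogen: Atom, acceptor: Atom, base: Atom,
                     base_neighbors: list[Atom]) -> float:
    """In-plane angle for an sp2 acceptor, on the same [90, 180] scale as phi.

    180° means the hydrogen lies exactly in the acceptor's sp2 plane; the
    deviation of H from the plane is subtracted from 180°.
    """
    others = [x for x in base_neighbors if x.serial != acceptor.serial]
    if not others:
        return 180.0
    v1 = acceptor.position - base.position
    v2 = others[0].position - base.position
    normal = np.cross(v1, v2)
    nn = np.linalg.norm(normal)
    if nn < 1e-9:
        return 180.0
    normal /= nn
    out_of_plane = abs(90.0 - angle_deg(hydrogen.position, acceptor.position,
                                        acceptor.position + normal))
    return 180.0 - out_of_plane


def mayo_energy(hb: HydrogenBond) -> float:
    """Mayo-style hydrogen bond energy (kcal/mol) from filled geometry.

    The angular factor F depends on the donor/acceptor hybridization:

    ========  ========  ==========================================
    donor     acceptor  F
    ========  ========  ==========================================
    sp3       sp3       cos^2(theta) * cos^2(phi - 109.5°)
    sp3       sp2       cos^2(theta) * cos^2(phi)
    sp2       sp3       cos^4(theta)
    sp2       sp2       cos^2(theta) * cos^2(max(phi, gamma))
    ========  ========  ==========================================

    Returns 0 when theta < 90° (no attractive geometry).
    """
    d = hb.d_DA
    if d <= 0:
        raise ValueError("donor-acceptor distance must be positive")
    if hb.theta < 90.0:
        return 0.0
    ratio = MAYO_D0 / d
    radial = 5.0 * ratio ** 12 - 6.0 * ratio ** 10
    ct2 = math.cos(math.radians(hb.theta)) ** 2
    pair = (hb.donor_hybrid, hb.acceptor_hybrid)
    if pair == ("sp3", "sp3"):
        f = ct2 * math.cos(math.radians(hb.phi - 109.5)) ** 2
    elif pair == ("sp3", "sp2"):
        f = ct2 * math.cos(math.radians(hb.phi)) ** 2
    elif pair == ("sp2", "sp3"):
        f = ct2 * ct2
    else:  # sp2 donor, sp2 acceptor
        f = ct2 * math.cos(math.radians(max(hb.phi, hb.gamma))) ** 2
    if f <= 0.0:
        return 0.0
    return MAYO_V0 * radial * f


_POLAR = {"N", "O", "S"}


def detect_hbonds(
    structure: MolecularStructure,
    bonds: list[CovalentBond],
    criteria: HBondCriteria | None = None,
) -> list[HydrogenBond]:
    """Detect hydrogen bonds among N/O/S donors and acceptors.

    One record is produced per (donor, hydrogen, acceptor) triple, so
    furcated configurations yield several records.  Candidates whose Mayo
    energy is positive (sterically repulsive geometry) are discarded, so
    every returned bond has energy <= 0.
    """
    criteria = criteria or HBondCriteria()
    criteria.validate()
    atoms = structure.atoms
    by_serial = {a.serial: a for a in atoms}
    graph = _bond_graph(structure, bonds)

    donors: list[tuple[Atom, Atom]] = []  # (D, H)
    for a in atoms:
        if a.element.upper() != "H":
            continue
        for nb in graph.neighbors(a.serial):
            d = by_serial[nb]
            if d.element.upper() in _POLAR:
                donors.append((d, a))

    acceptors = [a for a in atoms if a.element.upper() in _POLAR]
    if not donors or not acceptors:
        return []
    acc_tree = cKDTree(np.array([a.position for a in acceptors]))

    out: list[HydrogenBond] = []
    for d_atom, h_atom in donors:
        for idx in sorted(acc_tree.query_ball_point(h_atom.position,
                                                    criteria.d_HA_max)):
            a_atom = acceptors[idx]
            if a_atom.serial in (d_atom.serial, h_atom.serial):
                continue
            if graph.has_edge(a_atom.serial, h_atom.serial):
                continue
            if graph.has_edge(a_atom.serial, d_atom.serial):
                continue
            d_da = d_atom.distance_to(a_atom)
            d_ha = h_atom.distance_to(a_atom)
            if d_da > criteria.d_DA_max or d_ha > criteria.d_HA_max:
                continue
            theta = angle_deg(d_atom.position, h_atom.position, a_atom.position)
            if theta < criteria.theta_min:
                continue
            bases = [by_serial[s] for s in sorted(graph.neighbors(a_atom.serial))
                     if by_serial[s].element.upper() != "H"]
            if bases:
                phi = angle_deg(h_atom.position, a_atom.position,
                                bases[0].position)
            else:
                phi = 180.0
            acc_hyb = _hybridization(a_atom)
            gamma = phi
            if acc_hyb == "sp2" and bases:
                base_nbrs = [by_serial[s] for s in graph.neighbors(bases[0].serial)]
                gamma = _sp2_plane_gamma(h_atom, a_atom, bases[0], base_nbrs)
            hb = HydrogenBond(
                donor=d_atom, hydrogen=h_atom, acceptor=a_atom,
                acceptor_bases=bases, d_HA=d_ha, d_DA=d_da, theta=theta,
                phi=phi, gamma=gamma,
                donor_hybrid=_hybridization(d_atom), acceptor_hybrid=acc_hyb,
            )
            hb.energy = mayo_energy(hb)
            if hb.energy <= 0.0:
                out.append(hb)
    return out


def classify_hbond_configurations(
    hbonds: list[HydrogenBond], bonds: list[CovalentBond]
) -> ConfigurationCensus:
    """Label each hydrogen bond by its configuration and tally the census.

    Labels: ``furcated_donor(k)`` when the hydrogen takes part in k >= 2
    bonds; ``furcated_acceptor(k)`` when the acceptor takes part in k >= 2
    bonds; ``multi_base_acceptor`` when the acceptor has more than one
    covalent (heavy-atom) base; ``non_furcated`` excludes all others.
    """
    by_h: dict[int, int] = {}
    by_a: dict[int, int] = {}
    for hb in hbonds:
        by_h[hb.hydrogen.serial] = by_h.get(hb.hydrogen.serial, 0) + 1
        by_a[hb.acceptor.serial] = by_a.get(hb.acceptor.serial, 0) + 1

    labels: list[set[str]] = []
    counts: dict[str, int] = {}
    for hb in hbonds:
        lab: set[str] = set()
        kd = by_h[hb.hydrogen.serial]
        ka = by_a[hb.acceptor.serial]
        if kd >= 2:
            lab.add(f"furcated_donor({kd})")
        if ka >= 2:
            lab.add(f"furcated_acceptor({ka})")
        if len(hb.acceptor_bases) > 1:
            lab.add("multi_base_acceptor")
        if not lab:
            lab.add("non_furcated")
        hb.configuration = ",".join(sorted(lab))
        labels.append(lab)
        for name in lab:
            counts[name] = counts.get(name, 0) + 1
    total = len(hbonds)
    fractions = {k: v / total for k, v in counts.items()} if total else {}
    return ConfigurationCensus(total=total, labels=labels, counts=counts,
                               fractions=fractions)


# ---------------------------------------------------------------------------
# Hydrophobic interactions
# ---------------------------------------------------------------------------

def _pairs_within_k_bonds(graph: nx.Graph, serial: int, k: int) -> set[int]:
    return set(nx.single_source_shortest_path_length(graph, serial, cutoff=k))


def detect_hydrophobics_legacy(
    structure: MolecularStructure, bonds: list[CovalentBond]
) -> list[HydrophobicInteraction]:
    """Legacy heuristic: C-C, C-S or S-S pairs whose van der Waals surfaces
    lie within 0.25 Å, excluding same-residue pairs and pairs separated by
    three covalent bonds or fewer.  No energies are assigned."""
    graph = _bond_graph(structure, bonds)
    atoms = [a for a in structure.atoms if a.element.upper() in VDW_RADII]
    if not atoms:
        return []
    tree = cKDTree(np.array([a.position for a in atoms]))
    max_cut = 2 * max(VDW_RADII.values()) + _LEGACY_SURFACE_CUTOFF
    out: list[HydrophobicInteraction] = []
    for i, j in sorted(tree.query_pairs(max_cut)):
        a, b = atoms[i], atoms[j]
        if a.residue_key == b.residue_key:
            continue
        cut = (VDW_RADII[a.element.upper()] + VDW_RADII[b.element.upper()]
               + _LEGACY_SURFACE_CUTOFF)
        r = a.distance_to(b)
        if r > cut:
            continue
        if b.serial in _pairs_within_k_bonds(graph, a.serial, 3):
            continue
        out.append(HydrophobicInteraction(a, b, r=r, source="legacy"))
    return out


def lj_energy(r: float, epsilon: float, sigma: float) -> float:
    """Lennard-Jones 6-12 potential V = 4*eps*[(sigma/r)^12 - (sigma/r)^6]."""
    if r <= 0:
        raise ValueError("r must be positive")
    if epsilon < 0 or sigma <= 0:
        raise ValueError("epsilon must be >= 0 and sigma > 0")
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def detect_hydrophobics_lj(
    structure: MolecularStructure,
    bonds: list[CovalentBond],
    r_max: float = 6.0,
) -> list[HydrophobicInteraction]:
    """Score all heavy-atom pairs within ``r_max`` with the LJ 6-12 potential.

    Hydrogens are excluded, as are same-residue pairs and covalently
    connected 1-2 and 1-3 pairs.  Per-element epsilon/sigma (C, N, O, S)
    are combined with Lorentz-Berthelot mixing; elements without parameters
    are skipped.  Output order is deterministic (by serial pair) and does
    not depend on the spatial-search parameters.
    """
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    graph = _bond_graph(structure, bonds)
    atoms = [a for a in structure.atoms if a.element.upper() in _LJ_PARAMS]
    if not atoms:
        return []
    tree = cKDTree(np.array([a.position for a in atoms]))
    out: list[HydrophobicInteraction] = []
    for i, j in sorted(tree.query_pairs(r_max)):
        a, b = atoms[i], atoms[j]
        if a.residue_key == b.residue_key:
            continue
        if b.serial in _pairs_within_k_bonds(graph, a.serial, 2):
            continue  # 1-2 and 1-3 pairs are covalent geometry
        eps_a, rmin_a = _LJ_PARAMS[a.element.upper()]
        eps_b, rmin_b = _LJ_PARAMS[b.element.upper()]
        sigma = 0.5 * (rmin_a * _SIGMA_FACTOR + rmin_b * _SIGMA_FACTOR)
        epsilon = math.sqrt(eps_a * eps_b)
        r = a.distance_to(b)
        out.append(
            HydrophobicInteraction(
                a, b, r=r, epsilon=epsilon, sigma=sigma,
                energy=lj_energy(r, epsilon, sigma), source="lennard_jones",
            )
        )
    return out


def filter_by_energy(interactions: list, cutoff: float) -> tuple[list, list]:
    """Split interactions into (kept, excluded) by energy <= cutoff.

    Raises on sentinel (legacy, no-energy) interactions: those cannot be
    filtered by energy — use the Lennard-Jones method instead.
    """
    for it in interactions:
        if math.isnan(it.energy):
            raise ValueError(
                "interaction without energy (legacy heuristic); "
                "use the Lennard-Jones method for energy filtering"
            )
    kept = [it for it in interactions if it.energy <= cutoff]
    excluded = [it for it in interactions if it.energy > cutoff]
    return kept, excluded
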