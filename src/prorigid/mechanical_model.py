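"""Body-bar-hinge mechanical model of a molecule.

Bodies are built from the strong-bond graph (covalent bonds plus strong
hydrogen bonds): every multivalent atom becomes the central atom of one body
containing itself and its strong neighbors.  A strong bond whose two atoms
are both central makes the two bodies overlap in that bonded pair — a hinge,
locked when the bond is non-rotatable.  Weak hydrogen bonds and hydrophobic
interactions enter as bar constraints between bodies.

A bar whose endpoint is a central atom is placed, in the associated
multigraph, on the vertex of the body centered at that atom; non-central
endpoints belong to exactly one body, so there is no ambiguity.  This
resolves the bar-hinge concurrencies that arise for multi-base acceptors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from prorigid.interactions import (
    CovalentBond,
    HydrogenBond,
    HydrophobicInteraction,
    filter_by_energy,
)
from prorigid.pebble_game import AssociatedMultigraph
from prorigid.structure_io import Atom, MolecularStructure

__all__ = [
    "Body",
    "Hinge",
    "BarConstraint",
    "ModelingOptions",
    "BodyBarHingeModel",
    "build_bodies",
    "resolve_bar_endpoint",
    "build_model",
    "to_multigraph",
]

PER_PAIR_EDGE_CAP = 6  # a body pair is welded at 6 constraints; excess is trivially redundant


@dataclass
class Body:
    id: int
    central_atom: Atom | None
    member_atoms: list[Atom]

    @property
    def member_serials(self) -> frozenset[int]:
        return frozenset(a.serial for a in self.member_atoms)


@dataclass
class Hinge:
    atom_a: Atom
    atom_b: Atom
    body_a: int
    body_b: int
    locked: bool = False


@dataclass
class BarConstraint:
    endpoint_a: Atom
    endpoint_b: Atom
    body_a: int
    body_b: int
    multiplicity: int
    origin: str  # weak_hbond | hydrophobic_legacy | hydrophobic_lj | hinge_lock


_METHODS = {
    # method: (uses hbond cutoff, weak treatment, hydrophobic method)
    3: (False, "exclude", "legacy_2bar"),
    4: (True, "exclude", "legacy_2bar"),
    5: (True, "bar", "legacy_2bar"),
    6: (False, "exclude", "lj_1bar"),
    7: (True, "bar", "lj_1bar"),
}


@dataclass
class ModelingOptions:
    """Table-of-methods configuration for model building.

    Methods 3-7 are the structure-based decomposition methods; 1 (all-floppy)
    and 2 (all-rigid) ignore the structure and live in the scoring module as
    baselines.  ``hbond_cutoff=None`` means every detected H-bond is strong.
    """

    method: int = 3
    hbond_cutoff: float | None = None
    weak_hbond_treatment: str = "exclude"  # exclude | bar
    hydrophobic_method: str = "legacy_2bar"  # legacy_2bar | lj_1bar
    hydrophobic_cutoff: float = 0.0

    @classmethod
    def for_method(cls, method: int, hbond_cutoff: float | None = None,
                   hydrophobic_cutoff: float = 0.0) -> "ModelingOptions":
        if method not in _METHODS:
            raise ValueError(f"unknown decomposition method {method}; use 3..7")
        uses_cutoff, weak, phobic = _METHODS[method]
        if not uses_cutoff:
            hbond_cutoff = None
        return cls(method=method, hbond_cutoff=hbond_cutoff,
                   weak_hbond_treatment=weak, hydrophobic_method=phobic,
                   hydrophobic_cutoff=hydrophobic_cutoff)

    def validate(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown decomposition method {self.method}")
        uses_cutoff, weak, phobic = _METHODS[self.method]
        if self.weak_hbond_treatment != weak:
            raise ValueError(
                f"method {self.method} requires weak_hbond_treatment={weak!r}")
        if self.hydrophobic_method != phobic:
            raise ValueError(
                f"method {self.method} requires hydrophobic_method={phobic!r}")
        if not uses_cutoff and self.hbond_cutoff is not None:
            raise ValueError(
                f"method {self.method} takes no H-bond cutoff (all are strong)")


@dataclass
class BodyBarHingeModel:
    structure: MolecularStructure
    bodies: list[Body]
    hinges: list[Hinge]
    bars: list[BarConstraint]
    options: ModelingOptions | None = None
    n_intra_body_bars_dropped: int = 0

    def unlocked_hinge_pairs(self) -> set[frozenset[int]]:
        return {frozenset((h.atom_a.serial, h.atom_b.serial))
                for h in self.hinges if not h.locked}


def build_bodies(
    structure: MolecularStructure,
    strong_bonds: list[CovalentBond],
) -> tuple[list[Body], list[Hinge]]:
    """Derive bodies and hinges from the strong-bond graph.

    One body per multivalent atom (itself plus strong neighbors); a hinge for
    every strong bond whose atoms are both central, locked when the bond is
    non-rotatable.  Connected groups with no multivalent atom (isolated atoms
    or diatomics) become a single body with no central atom.
    """
    atoms = structure.atoms
    by_serial = {a.serial: a for a in atoms}
    nbrs: dict[int, set[int]] = {a.serial: set() for a in atoms}
    rotatable: dict[frozenset[int], bool] = {}
    for b in strong_bonds:
        nbrs[b.atom_a.serial].add(b.atom_b.serial)
        nbrs[b.atom_b.serial].add(b.atom_a.serial)
        key = frozenset((b.atom_a.serial, b.atom_b.serial))
        # a bond listed twice stays non-rotatable if any record says so
        rotatable[key] = rotatable.get(key, True) and b.rotatable

    bodies: list[Body] = []
    body_of_central: dict[int, int] = {}
    for a in atoms:
        if len(nbrs[a.serial]) >= 2:
            bid = len(bodies)
            members = [a] + [by_serial[s] for s in sorted(nbrs[a.serial])]
            bodies.append(Body(id=bid, central_atom=a, member_atoms=members))
            body_of_central[a.serial] = bid
    # leftover groups with no central atom: singletons and diatomics
    claimed = {a.serial for b in bodies for a in b.member_atoms}
    for a in atoms:
        if a.serial in claimed:
            continue
        group = [a] + [by_serial[s] for s in sorted(nbrs[a.serial])
                       if s not in claimed]
        bid = len(bodies)
        bodies.append(Body(id=bid, central_atom=None, member_atoms=group))
        claimed.update(x.serial for x in group)

    hinges: list[Hinge] = []
    for key, rot in sorted(rotatable.items(), key=lambda kv: sorted(kv[0])):
        s1, s2 = sorted(key)
        if s1 in body_of_central and s2 in body_of_central:
            hinges.append(
                Hinge(by_serial[s1], by_serial[s2],
                      body_of_central[s1], body_of_central[s2], locked=not rot)
            )
    return bodies, hinges


def resolve_bar_endpoint(atom: Atom, bodies: list[Body]) -> int:
    """Body id a bar endpoint attaches to.

    A central atom resolves to the body it is central to (even though it lies
    in several bodies); a non-central atom belongs to exactly one body.
    """
    containing = [b for b in bodies if atom.serial in b.member_serials]
    if not containing:
        raise ValueError(f"atom serial {atom.serial} belongs to no body")
    for b in containing:
        if b.central_atom is not None and b.central_atom.serial == atom.serial:
            return b.id
    if len(containing) > 1:
        # non-central atom in several bodies can only happen for hinge atoms,
        # which are central by construction; guard anyway
        raise ValueError(f"ambiguous body for non-central atom {atom.serial}")
    return containing[0].id


def _strong_pseudo_bond(hb: HydrogenBond) -> CovalentBond:
    # strong H-bond: the H-A contact joins body building like a bond, making
    # the hydrogen multivalent (it then centers a body containing D and A)
    return CovalentBond(hb.hydrogen, hb.acceptor, rotatable=True, kind="hbond")


def build_model(
    structure: MolecularStructure,
    covalent_bonds: list[CovalentBond],
    hbonds: list[HydrogenBond],
    hydrophobics: list[HydrophobicInteraction],
    options: ModelingOptions,
) -> BodyBarHingeModel:
    """Assemble the body-bar-hinge model under a decomposition method.

    Strong H-bonds (all of them when no cutoff applies, else those with
    energy <= cutoff) join body building; weak ones are excluded or become
    1-bar constraints between the hydrogen's and acceptor's bodies.
    Hydrophobic interactions contribute 2 bars each (legacy heuristic) or,
    for the Lennard-Jones method, 1 bar each after energy filtering.  Bars
    whose endpoints resolve to the same body constrain nothing and are
    dropped (counted).
    """
    options.validate()
    if options.hbond_cutoff is None:
        strong_hb, weak_hb = list(hbonds), []
    else:
        strong_hb = [h for h in hbonds if h.energy <= options.hbond_cutoff]
        weak_hb = [h for h in hbonds if h.energy > options.hbond_cutoff]

    strong_bonds = list(covalent_bonds) + [_strong_pseudo_bond(h)
                                           for h in strong_hb]
    bodies, hinges = build_bodies(structure, strong_bonds)

    bar_specs: list[tuple[Atom, Atom, int, str]] = []
    if options.weak_hbond_treatment == "bar":
        for h in weak_hb:
            bar_specs.append((h.hydrogen, h.acceptor, 1, "weak_hbond"))
    if options.hydrophobic_method == "legacy_2bar":
        for p in hydrophobics:
            bar_specs.append((p.atom_a, p.atom_b, 2, "hydrophobic_legacy"))
    else:
        if any(math.isnan(p.energy) for p in hydrophobics):
            raise ValueError("lj_1bar modeling needs energy-scored hydrophobics")
        kept, _ = filter_by_energy(hydrophobics, options.hydrophobic_cutoff)
        for p in kept:
            bar_specs.append((p.atom_a, p.atom_b, 1, "hydrophobic_lj"))

    bars: list[BarConstraint] = []
    dropped = 0
    for ea, eb, mult, origin in bar_specs:
        ba = resolve_bar_endpoint(ea, bodies)
        bb = resolve_bar_endpoint(eb, bodies)
        if ba == bb:
            dropped += 1
            continue
        bars.append(BarConstraint(ea, eb, ba, bb, multiplicity=mult,
                                  origin=origin))

    return BodyBarHingeModel(structure=structure, bodies=bodies, hinges=hinges,
                             bars=bars, options=options,
                             n_intra_body_bars_dropped=dropped)


def to_multigraph(model: BodyBarHingeModel) -> AssociatedMultigraph:
    """Associated multigraph: 5 parallel edges per hinge (6 when locked),
    ``multiplicity`` edges per bar, capped at 6 edges per body pair (the
    excess is trivially redundant and left out)."""
    graph = AssociatedMultigraph(vertices=[b.id for b in model.bodies])
    per_pair: dict[frozenset[int], int] = {}

    def add(u: int, v: int, count: int, origin: str) -> None:
        key = frozenset((u, v))
        have = per_pair.get(key, 0)
        allowed = max(0, min(count, PER_PAIR_EDGE_CAP - have))
        for _ in range(allowed):
            graph.add_edge(u, v, origin)
        for _ in range(count - allowed):
            graph.trivially_redundant.append((u, v, origin))
        per_pair[key] = have + allowed

    for h in model.hinges:
        add(h.body_a, h.body_b, 6 if h.locked else 5,
            "hinge_lock" if h.locked else "hinge")
    for b in model.bars:
        add(b.body_a, b.body_b, b.multiplicity, b.origin)
    return graph
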