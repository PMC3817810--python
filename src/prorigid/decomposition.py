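"""Residue-level decompositions and their text format.

Atom-level rigid clusters are converted to residue clusters with the
CA-hinge rule: a residue joins a cluster when its CA atom lies in the
cluster AND neither its C-CA nor its CA-N bond is an unlocked hinge in the
body-bar-hinge model (locked hinges prohibit rotation and do not
disqualify).  Residues claimed by several clusters go to the largest (ties:
first); residues claimed by none become singletons, so the result is always
a partition of the residue universe.

The file dialect (version 1) is one cluster per line::

    c1: A:1-5, A:9, B:3-7

Ranges are inclusive; items are chain:number with an optional insertion
code suffix (``A:52A``).  An optional ``universe:`` header line declares
items that become singletons when not listed in any cluster.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

__all__ = [
    "ResidueItem",
    "Decomposition",
    "to_residue_decomposition",
    "read_decomposition",
    "write_decomposition",
]


class ResidueItem(NamedTuple):
    chain_id: str
    residue_number: int
    insertion_code: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.residue_number}{self.insertion_code}"


class DecompositionFormatError(ValueError):
    pass


@dataclass
class Decomposition:
    """A partition of residue items into disjoint clusters (singletons allowed)."""

    items: list[ResidueItem]
    clusters: list[frozenset[ResidueItem]]

    def __post_init__(self) -> None:
        seen: set[ResidueItem] = set()
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster")
            overlap = seen & c
            if overlap:
                raise ValueError(f"items in several clusters: {sorted(overlap)}")
            seen |= c
        universe = set(self.items)
        if seen != universe:
            raise ValueError(
                "clusters do not cover the item universe exactly "
                f"(missing {sorted(universe - seen)[:5]}, "
                f"extra {sorted(seen - universe)[:5]})"
            )

    @property
    def n(self) -> int:
        return len(self.items)

    def cluster_of(self) -> dict[ResidueItem, frozenset[ResidueItem]]:
        out: dict[ResidueItem, frozenset[ResidueItem]] = {}
        for c in self.clusters:
            for item in c:
                out[item] = c
        return out

    @classmethod
    def from_clusters(cls, clusters: Iterable[Iterable[ResidueItem]],
                      universe: Iterable[ResidueItem] | None = None,
                      ) -> "Decomposition":
        cl = [frozenset(c) for c in clusters]
        listed = sorted({i for c in cl for i in c})
        if universe is None:
            items = listed
        else:
            items = sorted(set(universe) | set(listed))
            missing = set(items) - {i for c in cl for i in c}
            cl.extend(frozenset([i]) for i in sorted(missing))
        return cls(items=items, clusters=_canonical_order(cl))


def _canonical_order(clusters: list[frozenset[ResidueItem]]
                     ) -> list[frozenset[ResidueItem]]:
    return sorted(clusters, key=lambda c: (-len(c), min(c)))


def to_residue_decomposition(
    model,
    atom_clusters: list[set[int]],
    universe: list[ResidueItem],
) -> Decomposition:
    """Convert atom-level rigid clusters to a residue partition (CA-hinge rule).

    ``model`` is a BodyBarHingeModel built from the same structure;
    ``atom_clusters`` are sets of atom serials; ``universe`` lists every
    residue of the structure that should be scored.
    """
    structure = model.structure
    by_res = structure.atoms_by_residue()

    # An unlocked hinge still permits rotation only while its two bodies sit
    # in different rigid clusters; once both bodies are welded into one
    # cluster the rotation is inhibited by the constraint network and the
    # bond no longer disqualifies its residue.
    body_members = {b.id: b.member_serials for b in model.bodies}
    rotating: set[frozenset[int]] = set()
    for h in model.hinges:
        if h.locked:
            continue
        both = body_members[h.body_a] | body_members[h.body_b]
        if not any(both <= cluster for cluster in atom_clusters):
            rotating.add(frozenset((h.atom_a.serial, h.atom_b.serial)))

    # candidate cluster indices per residue
    claims: dict[ResidueItem, list[int]] = {}
    for item in universe:
        res_atoms = {a.name: a for a in by_res.get(tuple(item), [])}
        ca = res_atoms.get("CA")
        if ca is None:
            warnings.warn(f"residue {item} has no CA atom; left a singleton")
            continue
        c_at, n_at = res_atoms.get("C"), res_atoms.get("N")
        hinge_blocked = False
        for other in (c_at, n_at):
            if other is not None and \
                    frozenset((ca.serial, other.serial)) in rotating:
                hinge_blocked = True
        if hinge_blocked:
            continue
        for ci, cluster in enumerate(atom_clusters):
            if ca.serial in cluster:
                claims.setdefault(item, []).append(ci)

    # resolve multi-claims to the largest cluster (ties: first listed)
    assigned: dict[int, set[ResidueItem]] = {}
    for item, cands in claims.items():
        best = max(cands, key=lambda ci: (len(atom_clusters[ci]), -ci))
        assigned.setdefault(best, set()).add(item)

    clusters = [frozenset(v) for v in assigned.values() if v]
    placed = {i for c in clusters for i in c}
    clusters.extend(frozenset([i]) for i in universe if i not in placed)
    return Decomposition(items=sorted(universe),
                         clusters=_canonical_order(clusters))


# ---------------------------------------------------------------------------
# Text format
# ---------------------------------------------------------------------------

_ITEM_RE = re.compile(
    r"^\s*(?P<chain>[A-Za-z0-9]):(?P<a>-?\d+)(?P<ai>[A-Za-z]?)"
    r"(?:\s*-\s*(?P<b>-?\d+)(?P<bi>[A-Za-z]?))?\s*$"
)


def _parse_items(spec: str, line_no: int) -> list[ResidueItem]:
    items: list[ResidueItem] = []
    for token in spec.split(","):
        token = token.strip()
        if not token:
            continue
        m = _ITEM_RE.match(token)
        if not m:
            raise DecompositionFormatError(
                f"line {line_no}: cannot parse item {token!r}")
        chain = m.group("chain")
        a = int(m.group("a"))
        if m.group("b") is None:
            items.append(ResidueItem(chain, a, m.group("ai")))
        else:
            b = int(m.group("b"))
            if m.group("ai") or m.group("bi"):
                raise DecompositionFormatError(
                    f"line {line_no}: ranges cannot carry insertion codes")
            if b < a:
                raise DecompositionFormatError(
                    f"line {line_no}: reversed range {token!r}")
            items.extend(ResidueItem(chain, k) for k in range(a, b + 1))
    return items


def read_decomposition(path: str | Path) -> Decomposition:
    """Read the cluster-per-line dialect (see module docstring).

    Items listed in a ``universe:`` header but in no cluster become
    singletons.  An item in two clusters is a format error.
    """
    clusters: list[frozenset[ResidueItem]] = []
    universe: list[ResidueItem] = []
    seen: dict[ResidueItem, int] = {}
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise DecompositionFormatError(
                f"line {line_no}: expected 'name: items'")
        name, _, spec = line.partition(":")
        if name.strip().lower() == "universe":
            universe = _parse_items(spec, line_no)
            continue
        items = _parse_items(spec, line_no)
        for item in items:
            if item in seen:
                raise DecompositionFormatError(
                    f"line {line_no}: item {item} already in cluster "
                    f"{seen[item] + 1}")
            seen[item] = len(clusters)
        if items:
            clusters.append(frozenset(items))
    return Decomposition.from_clusters(clusters, universe=universe or None)


def write_decomposition(dec: Decomposition, path: str | Path) -> None:
    """Write the cluster-per-line dialect; read/write round-trips the partition."""
    lines = ["# decomposition format v1"]
    lines.append("universe: " + ", ".join(_compact(dec.items)))
    for k, cluster in enumerate(dec.clusters, start=1):
        lines.append(f"c{k}: " + ", ".join(_compact(sorted(cluster))))
    Path(path).write_text("\n".join(lines) + "\n")


def _compact(items: list[ResidueItem]) -> list[str]:
    """Collapse sorted items into chain:a-b range tokens where possible."""
    out: list[str] = []
    run: list[ResidueItem] = []
    for item in sorted(items):
        if (run and item.chain_id == run[-1].chain_id
                and not item.insertion_code and not run[-1].insertion_code
                and item.residue_number == run[-1].residue_number + 1):
            run.append(item)
        else:
            if run:
                out.append(_run_token(run))
            run = [item]
    if run:
        out.append(_run_token(run))
    return out


def _run_token(run: list[ResidueItem]) -> str:
    if len(run) == 1:
        return str(run[0])
    return f"{run[0].chain_id}:{run[0].residue_number}-{run[-1].residue_number}"
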