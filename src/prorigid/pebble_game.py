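"""(6,6)-pebble game on body-bar-hinge multigraphs.

Vertices are rigid bodies; each bar contributes one parallel edge and each
hinge five (six when locked).  An edge is independent exactly when it can be
added without violating the count ``|E(S)| <= 6|S| - 6`` on every vertex
subset S — decided here by the pebble game, and, for small graphs, by an
exhaustive subset-enumeration oracle used as ground truth in tests.

Rigid components are maximal vertex sets whose induced independent edges
reach 6n'-6.  Mutual rigidity of two bodies is decided by attempting to
gather seven pebbles on the pair: failure means some tight (fully
constrained) set contains both.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "AssociatedMultigraph",
    "PebbleGameResult",
    "run_pebble_game",
    "sparsity_oracle",
    "clusters_to_atoms",
]

K = 6  # pebbles per body: 6 spatial degrees of freedom
L = 6  # trivial motions of the whole framework

Edge = tuple[int, int, str]


@dataclass
class AssociatedMultigraph:
    """Multigraph of a body-bar-hinge framework.

    ``edges`` holds one entry per parallel edge as ``(u, v, origin)``;
    origin is a free-form label (``hinge``, ``hinge_lock``, ``weak_hbond``,
    ``hydrophobic_lj``, ...).
    """

    vertices: list[int]
    edges: list[Edge] = field(default_factory=list)
    # parallel edges beyond the 6-per-pair cap, recorded but never played
    trivially_redundant: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        vset = set(self.vertices)
        for u, v, _ in self.edges:
            if u == v:
                raise ValueError(f"self-loop at vertex {u}")
            if u not in vset or v not in vset:
                raise ValueError(f"edge ({u},{v}) references unknown vertex")

    def add_edge(self, u: int, v: int, origin: str = "") -> None:
        if u == v:
            raise ValueError(f"self-loop at vertex {u}")
        self.edges.append((u, v, origin))


@dataclass
class PebbleGameResult:
    independent_edges: list[Edge]
    redundant_edges: list[Edge]
    free_pebbles_per_vertex: dict[int, int]
    total_free_pebbles: int
    components: list[frozenset[int]]
    internal_dofs: int


class _PebbleState:
    """Oriented-graph state of the pebble game."""

    def __init__(self, vertices: Sequence[int]):
        self.pebbles = {v: K for v in vertices}
        # out[u][v] = number of accepted parallel edges oriented u -> v
        self.out: dict[int, dict[int, int]] = {v: {} for v in vertices}

    def _find_pebble(self, root: int, exclude: set[int]) -> bool:
        """DFS from root along edge orientations; if a free pebble is found
        outside ``exclude``, move it to root (reversing the path) and return
        True."""
        parent: dict[int, int] = {root: root}
        stack = [root]
        found = None
        while stack:
            x = stack.pop()
            for y in sorted(self.out[x]):
                if self.out[x][y] == 0 or y in parent:
                    continue
                parent[y] = x
                if self.pebbles[y] > 0 and y not in exclude:
                    found = y
                    stack.clear()
                    break
                stack.append(y)
        if found is None:
            return False
        # reverse the path, carrying the pebble back to the root
        self.pebbles[found] -= 1
        y = found
        while y != root:
            x = parent[y]
            self.out[x][y] -= 1
            self.out[y][x] = self.out[y].get(x, 0) + 1
            y = x
        self.pebbles[root] += 1
        return True

    def gather(self, u: int, v: int, target: int) -> bool:
        """Try to accumulate ``target`` pebbles on {u, v}."""
        exclude = {u, v}
        while self.pebbles[u] + self.pebbles[v] < target:
            if self.pebbles[u] < K and self._find_pebble(u, exclude):
                continue
            if self.pebbles[v] < K and self._find_pebble(v, exclude):
                continue
            return False
        return True

    def accept(self, u: int, v: int) -> None:
        if self.pebbles[u] == 0:  # both ends hold >=1 of the 7 gathered
            u, v = v, u
        self.pebbles[u] -= 1
        self.out[u][v] = self.out[u].get(v, 0) + 1


def run_pebble_game(graph: AssociatedMultigraph) -> PebbleGameResult:
    """Play the (6,6)-pebble game over the edges in input order.

    Each vertex starts with six pebbles.  An edge (u,v) is accepted as
    independent iff seven pebbles can be gathered onto {u,v}; acceptance
    consumes a pebble and orients the edge.  Rigid components are the
    equivalence classes of the pairwise "cannot gather seven" relation,
    restricted to connected vertices; bodies in no larger class are emitted
    as singleton components.
    """
    state = _PebbleState(graph.vertices)
    independent: list[Edge] = []
    redundant: list[Edge] = []
    for edge in graph.edges:
        u, v, _ = edge
        if state.gather(u, v, L + 1):
            state.accept(u, v)
            independent.append(edge)
        else:
            redundant.append(edge)

    total_free = sum(state.pebbles.values())

    # connected components of the underlying multigraph
    adj: dict[int, set[int]] = {v: set() for v in graph.vertices}
    for u, v, _ in graph.edges:
        adj[u].add(v)
        adj[v].add(u)
    seen: set[int] = set()
    conn: list[list[int]] = []
    for v in graph.vertices:
        if v in seen:
            continue
        comp, stack = [], [v]
        seen.add(v)
        while stack:
            x = stack.pop()
            comp.append(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        conn.append(sorted(comp))

    # rigid components: union-find over mutual rigidity within each
    # connected component (mutual rigidity is transitive for the 6|S|-6
    # count: overlapping rigid sets merge into a rigid set)
    components: list[frozenset[int]] = []
    for comp in conn:
        classes: list[list[int]] = []
        for v in comp:
            placed = False
            for cls in classes:
                if not state.gather(cls[0], v, L + 1):
                    cls.append(v)
                    placed = True
                    break
            if not placed:
                classes.append([v])
        components.extend(frozenset(c) for c in classes)
    components.sort(key=lambda c: (-len(c), min(c)))

    return PebbleGameResult(
        independent_edges=independent,
        redundant_edges=redundant,
        free_pebbles_per_vertex=dict(state.pebbles),
        total_free_pebbles=total_free,
        components=components,
        internal_dofs=total_free - L * len(conn),
    )


def sparsity_oracle(graph: AssociatedMultigraph) -> PebbleGameResult:
    """Exhaustive (6,6)-sparsity check for small graphs (|V| <= 12).

    Greedy matroid construction: an edge is independent iff adding it keeps
    every vertex subset S (|S| >= 2) at or below 6|S| - 6 induced edges.
    Components are the equivalence classes generated by the tight subsets.
    Identical result contract to :func:`run_pebble_game`.
    """
    verts = list(graph.vertices)
    n = len(verts)
    if n > 12:
        raise ValueError("sparsity_oracle is exhaustive; needs |V| <= 12")
    idx = {v: i for i, v in enumerate(verts)}

    subsets = [s for r in range(2, n + 1)
               for s in itertools.combinations(range(n), r)]
    count = {s: 0 for s in subsets}
    members = {s: set(s) for s in subsets}

    independent: list[Edge] = []
    redundant: list[Edge] = []
    for edge in graph.edges:
        u, v, _ = edge
        iu, iv = idx[u], idx[v]
        ok = True
        for s in subsets:
            m = members[s]
            if iu in m and iv in m and count[s] + 1 > K * len(s) - L:
                ok = False
                break
        if ok:
            independent.append(edge)
            for s in subsets:
                m = members[s]
                if iu in m and iv in m:
                    count[s] += 1
        else:
            redundant.append(edge)

    # free pebbles: 6 per vertex minus independent edges charged to their tail
    # (the oracle has no orientations; only totals are contractually shared)
    total_free = K * n - len(independent)
    per_vertex: dict[int, int] = {v: K for v in verts}
    for u, v, _ in independent:
        per_vertex[u] -= 1  # arbitrary but conserved charging

    # tight subsets are rigid; merge overlapping ones (transitivity)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rigid_any = [False] * n
    for s in subsets:
        if count[s] == K * len(s) - L:
            first = s[0]
            for other in s[1:]:
                parent[find(other)] = find(first)
            for i in s:
                rigid_any[i] = True
    groups: dict[int, set[int]] = {}
    for i in range(n):
        if rigid_any[i]:
            groups.setdefault(find(i), set()).add(i)
    components = [frozenset(verts[i] for i in g) for g in groups.values()]
    for i in range(n):
        if not rigid_any[i]:
            components.append(frozenset([verts[i]]))
    components.sort(key=lambda c: (-len(c), min(c)))

    # connected components for the DOF count
    adj = {v: set() for v in verts}
    for u, v, _ in graph.edges:
        adj[u].add(v)
        adj[v].add(u)
    seen: set[int] = set()
    n_conn = 0
    for v in verts:
        if v in seen:
            continue
        n_conn += 1
        stack = [v]
        seen.add(v)
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)

    return PebbleGameResult(
        independent_edges=independent,
        redundant_edges=redundant,
        free_pebbles_per_vertex=per_vertex,
        total_free_pebbles=total_free,
        components=components,
        internal_dofs=total_free - L * n_conn,
    )


def clusters_to_atoms(result: PebbleGameResult, model) -> list[set]:
    """Map graph-level rigid components to atom sets (union of body atoms).

    Clusters may overlap in hinge atoms.  ``model`` is a
    :class:`~prorigid.mechanical_model.BodyBarHingeModel`.
    """
    body_by_id = {b.id: b for b in model.bodies}
    out: list[set] = []
    for comp in result.components:
        atoms: set = set()
        for vid in comp:
            if vid not in body_by_id:
                raise ValueError(f"component vertex {vid} not in model")
            atoms |= set(body_by_id[vid].member_serials)
        out.append(atoms)
    return out


def write_edge_list(graph: AssociatedMultigraph, path) -> None:
    """Text export: one line per parallel edge, ``u<TAB>v<TAB>origin``."""
    with open(path, "w") as fh:
        fh.write(f"# vertices: {' '.join(map(str, graph.vertices))}\n")
        for u, v, origin in graph.edges:
            fh.write(f"{u}\t{v}\t{origin}\n")


def read_edge_list(path) -> AssociatedMultigraph:
    vertices: list[int] = []
    edges: list[Edge] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "vertices:" in line:
                    vertices = [int(x) for x in
                                line.split("vertices:")[1].split()]
                continue
            parts = line.split("\t")
            edges.append((int(parts[0]), int(parts[1]),
                          parts[2] if len(parts) > 2 else ""))
    if not vertices:
        vertices = sorted({x for u, v, _ in edges for x in (u, v)})
    return AssociatedMultigraph(vertices=vertices, edges=edges)
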