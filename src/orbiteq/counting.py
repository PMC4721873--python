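"""Reference orbit counting on explored graphs.

Two independent routes produce, for every vertex of an explored graph, the
number of times it touches each orbit of order n:

* :func:`brute_force_counts` enumerates every connected induced subgraph of
  order n and classifies each member vertex's position -- the definition
  itself, used as the oracle;
* :func:`solve_counts` counts only order-(n-1) representative instances and
  common neighbors, then back-substitutes the generated equation system in
  descending orbit order, with the complete graphlet counted directly by
  clique enumeration.

Both are exhaustive reference implementations: correctness and exact integer
agreement are the goal, not throughput on large networks.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations

from . import _perm
from .errors import InputError, ConsistencyError
from .equations import EquationSystem
from .graphlets import OrbitRepresentative
from .naming import GraphletCatalog


class ExploredGraph:
    """Undirected simple graph with arbitrary hashable vertex identifiers.

    Vertices keep their first-seen order, which makes every traversal and
    output deterministic for a fixed input.
    """

    def __init__(self):
        self._vertices: list = []
        self._index: dict = {}
        self.adjacency: dict = {}

    @property
    def vertices(self) -> tuple:
        return tuple(self._vertices)

    @property
    def n_vertices(self) -> int:
        return len(self._vertices)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.adjacency.values()) // 2

    def add_vertex(self, v) -> None:
        if v not in self._index:
            self._index[v] = len(self._vertices)
            self._vertices.append(v)
            self.adjacency[v] = set()

    def add_edge(self, u, v) -> None:
        if u == v:
            raise InputError(f"self-loop on vertex {u!r}")
        self.add_vertex(u)
        self.add_vertex(v)
        self.adjacency[u].add(v)
        self.adjacency[v].add(u)

    def has_edge(self, u, v) -> bool:
        return v in self.adjacency.get(u, ())

    def index(self, v) -> int:
        return self._index[v]

    @classmethod
    def from_edges(cls, edges, vertices=()) -> "ExploredGraph":
        g = cls()
        for v in vertices:
            g.add_vertex(v)
        for u, v in edges:
            g.add_edge(u, v)
        return g


def random_graph(n_vertices: int, edge_probability: float, seed: int) -> ExploredGraph:
    """Seeded Erdos-Renyi-style test graph; identical seed, identical graph."""
    if not 0 <= edge_probability <= 1:
        raise InputError("edge probability must be in [0, 1]")
    rng = random.Random(seed)
    g = ExploredGraph()
    for v in range(n_vertices):
        g.add_vertex(v)
    for u in range(n_vertices):
        for v in range(u + 1, n_vertices):
            if rng.random() < edge_probability:
                g.add_edge(u, v)
    return g


def common_neighbors(g: ExploredGraph, s) -> int:
    """Number of explored-graph vertices adjacent to every member of ``s``.

    Members of ``s`` are excluded automatically (no self-loops).
    """
    it = iter(s)
    try:
        first = next(it)
    except StopIteration:
        raise InputError("common neighbor set must be nonempty") from None
    if first not in g.adjacency:
        raise InputError(f"unknown vertex {first!r}")
    acc = g.adjacency[first]
    for v in it:
        if v not in g.adjacency:
            raise InputError(f"unknown vertex {v!r}")
        acc = acc & g.adjacency[v]
        if not acc:
            return 0
    return len(acc)


def _search_order(rep: OrbitRepresentative) -> list[int]:
    """Vertex placement order: 0 first, then lowest index with a placed neighbor."""
    adj = rep.graphlet.adjacency
    order = [0]
    placed = {0}
    while len(order) < rep.order:
        for v in range(rep.order):
            if v not in placed and adj[v] & placed:
                order.append(v)
                placed.add(v)
                break
        else:  # pragma: no cover - representatives are connected
            raise ConsistencyError("representative is disconnected")
    return order


def rep_instances(
    g: ExploredGraph, anchor, r: OrbitRepresentative
) -> list[tuple]:
    """All instances of representative ``r`` anchored at ``anchor``.

    An instance maps the representative's vertices injectively onto explored
    vertices, vertex 0 onto the anchor, preserving edges *and* non-edges
    (induced-subgraph semantics).  Exactly one mapping is kept per
    equivalence class under the representative's automorphisms fixing vertex
    0 -- the "unique ordering" of interchangeable vertices -- namely the one
    whose image tuple is smallest in the graph's vertex order.

    Returns image tuples indexed by representative vertex.
    """
    if anchor not in g.adjacency:
        raise InputError(f"unknown vertex {anchor!r}")
    k = r.order
    rep_adj = r.graphlet.adjacency
    if k >= 2 and anchor not in g.adjacency:
        return []
    seq = _search_order(r)
    images: list = [None] * k
    images[0] = anchor
    used = {anchor}
    found: list[tuple] = []

    def backtrack(i: int) -> None:
        if i == len(seq):
            found.append(tuple(images))
            return
        u = seq[i]
        placed = seq[:i]
        nbr_placed = [w for w in placed if w in rep_adj[u]]
        cands = set(g.adjacency[images[nbr_placed[0]]])
        for w in nbr_placed[1:]:
            cands &= g.adjacency[images[w]]
        for cand in sorted(cands, key=g.index):
            if cand in used:
                continue
            ok = True
            for w in placed:
                if w not in rep_adj[u] and cand in g.adjacency[images[w]]:
                    ok = False
                    break
            if ok:
                images[u] = cand
                used.add(cand)
                backtrack(i + 1)
                used.discard(cand)
        images[u] = None

    if k == 1:
        return [(anchor,)]
    backtrack(1)
    auts = _perm.automorphism_perms(k, r.graphlet.code, fix_zero=True)
    if len(auts) == 1:
        return found
    keep = []
    idx = g.index
    for imgs in found:
        key = tuple(idx(v) for v in imgs)
        if all(tuple(key[p[i]] for i in range(k)) >= key for p in auts):
            keep.append(imgs)
    return keep


def count_complete(g: ExploredGraph, order: int) -> dict:
    """Per vertex, the number of order-``order`` cliques containing it."""
    if order < 2:
        raise InputError("clique order must be >= 2")
    counts = {v: 0 for v in g.vertices}
    verts = g.vertices
    idx = g.index

    def extend(clique: list, cands: list) -> None:
        if len(clique) == order:
            for v in clique:
                counts[v] += 1
            return
        need = order - len(clique)
        for i, v in enumerate(cands):
            if len(cands) - i < need:
                break
            extend(clique + [v], [w for w in cands[i + 1 :] if w in g.adjacency[v]])

    extend([], sorted(verts, key=idx))
    return counts


@dataclass
class OrbitCountTable:
    """Per-vertex integer counts for every orbit id of one order."""

    order: int
    n_orbits: int
    counts: dict  # vertex -> list[int] indexed by orbit id

    def get(self, vertex, orbit: int) -> int:
        return self.counts[vertex][orbit]

    def row(self, vertex) -> list[int]:
        return list(self.counts[vertex])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OrbitCountTable)
            and self.order == other.order
            and self.n_orbits == other.n_orbits
            and self.counts == other.counts
        )

    def to_tsv(self) -> str:
        header = "vertex\t" + "\t".join(f"o{i}" for i in range(self.n_orbits))
        lines = [header]
        for v, row in self.counts.items():
            lines.append(str(v) + "\t" + "\t".join(str(c) for c in row))
        return "\n".join(lines) + "\n"

    def to_json(self) -> dict:
        return {
            "order": self.order,
            "orbits": list(range(self.n_orbits)),
            "counts": {str(v): list(row) for v, row in self.counts.items()},
        }

    @staticmethod
    def from_json(obj: dict) -> "OrbitCountTable":
        return OrbitCountTable(
            obj["order"],
            len(obj["orbits"]),
            {v: list(row) for v, row in obj["counts"].items()},
        )


def brute_force_counts(
    g: ExploredGraph, order: int, catalog: GraphletCatalog
) -> OrbitCountTable:
    """Oracle counter: classify every connected induced subgraph directly.

    For every connected induced subgraph S with |S| = order and every vertex
    v in S, the orbit of v's position in S gains one count.  Classification
    goes through the catalog's canonical machinery, cached per induced edge
    pattern, and is entirely independent of the equation system.
    """
    if order != catalog.order:
        raise InputError("catalog order mismatch")
    verts = g.vertices
    table = OrbitCountTable(order, catalog.n_orbits, {v: [0] * catalog.n_orbits for v in verts})
    length = _perm.code_length(order)
    adj = g.adjacency
    for combo in combinations(verts, order):
        code = 0
        j = 0
        for ri in range(1, order):
            vr = combo[ri]
            for ci in range(ri):
                if combo[ci] in adj[vr]:
                    code |= 1 << (length - 1 - j)
                j += 1
        orbits = catalog.classify_vertices(code)
        if orbits is None:
            continue
        for local, v in enumerate(combo):
            table.counts[v][orbits[local]] += 1
    return table


def solve_counts(
    g: ExploredGraph, system: EquationSystem, catalog: GraphletCatalog
) -> OrbitCountTable:
    """Count orbits by solving the equation system per vertex.

    The complete graphlet's orbit comes from clique counting; the remaining
    orbits come from back-substitution in descending lowest-orbit order.
    Every division by a leading coefficient must be exact -- a remainder
    signals an equation-generation bug and raises.
    """
    order = system.order
    if order != catalog.order:
        raise InputError("catalog order mismatch")
    for eq in system.equations.values():
        if eq.start_rep is None:
            raise InputError("system lacks start representatives (reload with a catalog)")
    n_orbits = catalog.n_orbits
    complete_orbit = n_orbits - 1
    table = OrbitCountTable(order, n_orbits, {v: [0] * n_orbits for v in g.vertices})
    cliques = count_complete(g, order)
    keys = system.sorted_keys_descending()
    for v in g.vertices:
        row = table.counts[v]
        row[complete_orbit] = cliques[v]
        inst_cache: dict = {}
        for key in keys:
            eq = system.equations[key]
            insts = inst_cache.get(eq.start_orbit)
            if insts is None:
                insts = rep_instances(g, v, eq.start_rep)
                inst_cache[eq.start_orbit] = insts
            rhs = 0
            for imgs in insts:
                for t in eq.rhs_terms:
                    rhs += common_neighbors(g, [imgs[i] for i in t.subset]) - t.minus
            for term in eq.lhs[1:]:
                rhs -= term.coeff * row[term.orbit]
            q, rem = divmod(rhs, eq.lhs[0].coeff)
            if rem:
                raise ConsistencyError(
                    f"non-integer solution for orbit {key} at vertex {v!r}"
                )
            row[key] = q
    return table
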