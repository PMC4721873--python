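"""Graphlets, orbit representatives and their symmetry machinery.

A *graphlet* is a small connected simple graph on vertices 0..n-1, compared
up to isomorphism.  An *orbit representative* is a graphlet with vertex 0
marked; two representatives are the same orbit exactly when some isomorphism
maps one onto the other while keeping vertex 0 in place.  The vertices of a
representative fall into *suborbits* -- equivalence classes under
automorphisms that pin the marked vertex -- which refine the graphlet's
ordinary automorphism orbits and drive the multiplicities in the counting
equations.

All symmetry computations enumerate permutations exhaustively: n! for
graphlets, (n-1)! for representatives.  That is deliberate; the tool's
working range is small orders, where storing every permuted edge set is
cheap and keeps every comparison exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

from . import _perm
from .errors import InputError

#: Exhaustive permutation work grows factorially; beyond this order the
#: enumeration APIs refuse to run.
MAX_ORDER = 7

Edge = tuple[int, int]
EdgeSet = frozenset[Edge]
#: Partition of 0..n-1 into disjoint blocks, each sorted, blocks ordered by
#: their smallest member.
VertexPartition = tuple[tuple[int, ...], ...]


def _normalize_edges(order: int, edges) -> EdgeSet:
    out = set()
    for e in edges:
        u, v = e
        if u == v:
            raise InputError(f"self-loop on vertex {u}")
        if not (0 <= u < order and 0 <= v < order):
            raise InputError(f"edge {{{u},{v}}} out of range for order {order}")
        out.add((min(u, v), max(u, v)))
    return frozenset(out)


@dataclass(frozen=True)
class Graphlet:
    """A simple graph on vertices 0..n-1 stored as a set of (low, high) pairs.

    Equality and hashing are structural (same labeled edge set), not
    isomorphism; use :func:`orbiteq.naming.canonical_string` to compare up to
    relabeling.
    """

    order: int
    edges: EdgeSet

    @property
    def size(self) -> int:
        return len(self.edges)

    @cached_property
    def code(self) -> int:
        return _perm.code_from_edges(self.order, self.edges)

    @cached_property
    def adjacency(self) -> tuple[frozenset[int], ...]:
        nbr = [set() for _ in range(self.order)]
        for u, v in self.edges:
            nbr[u].add(v)
            nbr[v].add(u)
        return tuple(frozenset(s) for s in nbr)

    def has_edge(self, u: int, v: int) -> bool:
        return (min(u, v), max(u, v)) in self.edges

    def sorted_edges(self) -> list[list[int]]:
        return [list(e) for e in sorted(self.edges)]

    def to_json(self) -> dict:
        return {"order": self.order, "edges": self.sorted_edges()}

    @staticmethod
    def from_json(obj: dict) -> "Graphlet":
        return make_graphlet(obj["order"], [tuple(e) for e in obj["edges"]], strict=False)


def make_graphlet(order: int, edges, *, strict: bool = True) -> Graphlet:
    """Validate and build a graphlet.

    With ``strict=True`` (the default) the graph must be connected, as a
    graphlet is by definition.  ``strict=False`` admits disconnected
    intermediates; the enumeration and equation APIs never emit those.
    """
    if order < 1:
        raise InputError(f"order must be >= 1, got {order}")
    g = Graphlet(order, _normalize_edges(order, edges))
    if strict and not is_connected(g):
        raise InputError("graphlet must be connected (use strict=False to relax)")
    return g


def is_connected(g: Graphlet) -> bool:
    """True iff a single component covers every vertex (order 1 is connected)."""
    return _perm.connected_code(g.order, g.code)


@dataclass(frozen=True)
class OrbitRepresentative:
    """A graphlet with vertex 0 marked.

    The marked vertex is always vertex 0 by convention; permutation-based
    equality never moves it.
    """

    graphlet: Graphlet
    marked: int = field(default=0, init=False)

    def __post_init__(self):
        g = self.graphlet
        if g.order >= 2 and not g.adjacency[0]:
            raise InputError("marked vertex 0 must touch at least one edge")

    @property
    def order(self) -> int:
        return self.graphlet.order

    def to_json(self) -> dict:
        d = self.graphlet.to_json()
        d["marked"] = 0
        return d

    @staticmethod
    def from_json(obj: dict) -> "OrbitRepresentative":
        return OrbitRepresentative(Graphlet.from_json(obj))


def make_representative(order: int, edges) -> OrbitRepresentative:
    return OrbitRepresentative(make_graphlet(order, edges))


def _apply_perm_edges(edges: EdgeSet, perm) -> EdgeSet:
    return frozenset(
        (min(perm[u], perm[v]), max(perm[u], perm[v])) for u, v in edges
    )


def isomorphic_edge_sets(g: Graphlet) -> set[EdgeSet]:
    """All distinct edge sets obtained by permuting the vertices of ``g``.

    This is the stored-permutation view of the isomorphism class: ``g``'s own
    edge set is always a member, and the set is closed under further
    permutation.
    """
    return {_apply_perm_edges(g.edges, p) for p in _perm.all_perms(g.order)}


def rep_edge_sets(r: OrbitRepresentative) -> set[EdgeSet]:
    """As :func:`isomorphic_edge_sets`, but permutations keep vertex 0 fixed."""
    g = r.graphlet
    return {_apply_perm_edges(g.edges, p) for p in _perm.perms_fixing_zero(g.order)}


def _orbit_partition(order: int, perms) -> VertexPartition:
    parent = list(range(order))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for perm in perms:
        for v in range(order):
            a, b = find(v), find(perm[v])
            if a != b:
                parent[max(a, b)] = min(a, b)
    blocks: dict[int, list[int]] = {}
    for v in range(order):
        blocks.setdefault(find(v), []).append(v)
    return tuple(tuple(sorted(b)) for _, b in sorted(blocks.items()))


def vertex_orbits(g: Graphlet) -> VertexPartition:
    """Automorphism orbits of ``g``'s vertices.

    Collected by running every edge-set-preserving permutation and merging
    the vertices it maps onto each other.
    """
    return _orbit_partition(
        g.order, _perm.automorphism_perms(g.order, g.code)
    )


def suborbits(r: OrbitRepresentative) -> VertexPartition:
    """Orbits of ``r``'s vertices under automorphisms that fix vertex 0.

    Vertex 0 is always a singleton block.  Suborbits refine the graphlet's
    orbits: vertices equivalent as seen from the marked vertex.
    """
    g = r.graphlet
    return _orbit_partition(
        g.order, _perm.automorphism_perms(g.order, g.code, fix_zero=True)
    )


def extend_with_vertex(
    r: OrbitRepresentative, neighbors: frozenset[int] | set[int]
) -> OrbitRepresentative:
    """Add one vertex (receiving index = old order) joined to ``neighbors``."""
    g = r.graphlet
    nbrs = frozenset(neighbors)
    if not nbrs:
        raise InputError("new vertex needs at least one neighbor")
    if not all(0 <= v < g.order for v in nbrs):
        raise InputError("neighbor index out of range")
    new = g.order
    edges = set(g.edges) | {(v, new) for v in nbrs}
    return OrbitRepresentative(Graphlet(new + 1, frozenset(edges)))


def add_edges(g, new_edges):
    """Add edges between existing vertices; works on graphlets and representatives."""
    if isinstance(g, OrbitRepresentative):
        return OrbitRepresentative(add_edges(g.graphlet, new_edges))
    extra = _normalize_edges(g.order, new_edges)
    dup = extra & g.edges
    if dup:
        raise InputError(f"edges already present: {sorted(dup)}")
    return Graphlet(g.order, g.edges | extra)


def relabel(g: Graphlet, perm) -> Graphlet:
    """Apply a vertex permutation (old label -> new label)."""
    return Graphlet(g.order, _apply_perm_edges(g.edges, tuple(perm)))
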