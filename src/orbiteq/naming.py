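"""Canonical naming, enumeration and numbering of graphlets and orbits.

Every graphlet is encoded as the string of its strict lower-triangular
adjacency bits (rows 1..n-1, columns 0..r-1, row-major).  The canonical
string is the lexicographically smallest encoding over all vertex
permutations; it is a complete isomorphism invariant and, because an added
edge can only flip a 0 to a 1, it orders graphlets compatibly with edge
addition.  Sorting canonical strings therefore yields the graphlet
numbering, and within each graphlet orbits are numbered in the order their
vertices first appear in the canonical labeling.

Enumeration runs a binary counter over all 2^(n(n-1)/2) strings, keeps the
connected decodings and deduplicates by canonical string.  For order 6 this
means 32,768 strings against 720 permutations each; that inner product is
vectorized with numpy.  Orders above 7 are refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _perm
from .errors import CapabilityError, InputError, ConsistencyError
from .graphlets import (
    MAX_ORDER,
    Graphlet,
    OrbitRepresentative,
    VertexPartition,
    is_connected,
    relabel,
    vertex_orbits,
)


def triangular_string(g: Graphlet, perm) -> str:
    """Triangle bit string of ``g`` after relabeling vertices by ``perm``."""
    perm = tuple(perm)
    if sorted(perm) != list(range(g.order)):
        raise InputError("perm must be a bijection on 0..n-1")
    inv = [0] * g.order
    for old, new in enumerate(perm):
        inv[new] = old
    return "".join(
        "1" if g.has_edge(inv[r], inv[c]) else "0"
        for r, c in _perm.pair_positions(g.order)
    )


def _code_to_string(order: int, code: int) -> str:
    length = _perm.code_length(order)
    return format(code, f"0{length}b") if length else ""


def canonical_string(g: Graphlet) -> str:
    """Lexicographically smallest triangular string over all n! relabelings."""
    return _code_to_string(g.order, _perm.canonical_code(g.order, g.code))


@dataclass(frozen=True)
class CatalogOrbit:
    global_id: int
    members: tuple[int, ...]  # vertex labels in the graphlet's canonical labeling
    representative: OrbitRepresentative


@dataclass(frozen=True)
class CatalogEntry:
    id: int
    canonical: str
    graphlet: Graphlet  # stored in its canonical labeling
    orbits: tuple[CatalogOrbit, ...]


class GraphletCatalog:
    """All graphlets of one order, named and numbered canonically.

    Graphlet ids follow ascending canonical-string order; orbit ids are
    consecutive across the catalog, grouped by graphlet, intra-graphlet in
    order of first vertex appearance.  Numbering restarts at 0 for each
    order, since equations only ever mix orbits of a single order.
    """

    def __init__(self, order: int, entries: tuple[CatalogEntry, ...]):
        self.order = order
        self.entries = entries
        self._by_canon = {int(e.canonical, 2) if e.canonical else 0: e for e in entries}
        self._orbit_by_rep_code: dict[int, int] = {}
        self._orbit_of_label: dict[int, tuple[int, ...]] = {}
        for e in entries:
            label_map = [0] * order
            for orb in e.orbits:
                code0 = _perm.canonical_code(
                    order, orb.representative.graphlet.code, fix_zero=True
                )
                self._orbit_by_rep_code[code0] = orb.global_id
                for v in orb.members:
                    label_map[v] = orb.global_id
            self._orbit_of_label[e.id] = tuple(label_map)
        self._vertex_class_cache: dict[int, tuple[int, ...] | None] = {}

    @property
    def n_graphlets(self) -> int:
        return len(self.entries)

    @property
    def n_orbits(self) -> int:
        return sum(len(e.orbits) for e in self.entries)

    def orbit_representatives(self):
        for e in self.entries:
            yield from e.orbits

    def classify_graphlet(self, g: Graphlet) -> int:
        if g.order != self.order:
            raise InputError(f"graphlet order {g.order} != catalog order {self.order}")
        if not is_connected(g):
            raise InputError("cannot classify a disconnected graph")
        canon = _perm.canonical_code(g.order, g.code)
        return self._by_canon[canon].id

    def classify_orbit(self, r: OrbitRepresentative) -> int:
        if r.order != self.order:
            raise InputError(f"representative order {r.order} != catalog order {self.order}")
        code0 = _perm.canonical_code(self.order, r.graphlet.code, fix_zero=True)
        try:
            return self._orbit_by_rep_code[code0]
        except KeyError:
            raise ConsistencyError(
                "representative matches no catalog orbit"
            ) from None

    def classify_vertices(self, code: int) -> tuple[int, ...] | None:
        """Per-vertex global orbit ids for a labeled order-n graph given as a code.

        Returns None for disconnected graphs.  Used by the brute-force
        counter, which looks up every induced subgraph it meets.
        """
        cached = self._vertex_class_cache.get(code, "miss")
        if cached != "miss":
            return cached
        if not _perm.connected_code(self.order, code):
            self._vertex_class_cache[code] = None
            return None
        canon, perm = _perm.canonical_code_perm(self.order, code)
        labels = self._orbit_of_label[self._by_canon[canon].id]
        # vertex v plays canonical label perm[v]
        result = tuple(labels[perm[v]] for v in range(self.order))
        self._vertex_class_cache[code] = result
        return result

    def to_json(self) -> dict:
        return {
            "order": self.order,
            "n_graphlets": self.n_graphlets,
            "n_orbits": self.n_orbits,
            "graphlets": [
                {
                    "id": e.id,
                    "canonical_string": e.canonical,
                    "edges": e.graphlet.sorted_edges(),
                    "orbits": [
                        {
                            "global_id": o.global_id,
                            "member_vertices": list(o.members),
                            "representative_edges": o.representative.graphlet.sorted_edges(),
                        }
                        for o in e.orbits
                    ],
                }
                for e in self.entries
            ],
        }


def _connected_canonicals_python(order: int) -> set[int]:
    found = set()
    for code in range(1 << _perm.code_length(order)):
        if _perm.connected_code(order, code):
            found.add(_perm.canonical_code(order, code))
    return found


def _connected_canonicals_numpy(order: int) -> set[int]:
    """Vectorized canonicalization: min over permutations for every connected code."""
    length = _perm.code_length(order)
    masks = np.array(
        [c for c in range(1 << length) if _perm.connected_code(order, c)],
        dtype=np.int64,
    )
    shifts = np.arange(length - 1, -1, -1, dtype=np.int64)
    bits = ((masks[:, None] >> shifts[None, :]) & 1).astype(np.uint8)
    posmaps = np.array(_perm.position_maps(order), dtype=np.int64)
    weights = (1 << shifts).astype(np.int64)
    canon = np.empty(len(masks), dtype=np.int64)
    chunk = 1024
    for lo in range(0, len(masks), chunk):
        part = bits[lo : lo + chunk]  # (c, L)
        permuted = part[:, posmaps]  # (c, P, L)
        vals = permuted.astype(np.int64) @ weights  # (c, P)
        canon[lo : lo + chunk] = vals.min(axis=1)
    return set(int(c) for c in canon)


def enumerate_graphlets(order: int, *, with_orbits: bool = True) -> GraphletCatalog:
    """Enumerate all graphlets of one order, in canonical ascending order.

    Iterates every triangle bit string with a binary counter, decodes it,
    keeps connected graphs and deduplicates by canonical string.  Orbit
    numbering is filled in unless ``with_orbits=False``.
    """
    if order < 1:
        raise InputError(f"order must be >= 1, got {order}")
    if order > MAX_ORDER:
        raise CapabilityError(
            f"order {order} exceeds the factorial-canonicalization bound ({MAX_ORDER})"
        )
    if order >= 6:
        canonicals = _connected_canonicals_numpy(order)
    else:
        canonicals = _connected_canonicals_python(order)
    entries = []
    for gid, canon in enumerate(sorted(canonicals)):
        g = Graphlet(order, _perm.edges_from_code(order, canon))
        entries.append(CatalogEntry(gid, _code_to_string(order, canon), g, ()))
    catalog = GraphletCatalog(order, tuple(entries))
    if with_orbits:
        catalog = orbit_numbering(catalog)
    return catalog


def orbit_numbering(catalog: GraphletCatalog) -> GraphletCatalog:
    """Assign global orbit ids and materialize one representative per orbit.

    Within each graphlet (in its canonical labeling) orbits are ordered by
    their minimum vertex label; global ids run consecutively through the
    catalog.  Each representative is built by swapping the orbit's minimal
    vertex with label 0.
    """
    entries = []
    gid_counter = 0
    for e in catalog.entries:
        blocks: VertexPartition = vertex_orbits(e.graphlet)
        orbits = []
        for block in blocks:  # blocks already sorted by min member
            m = block[0]
            perm = list(range(catalog.order))
            perm[0], perm[m] = perm[m], perm[0]
            rep = OrbitRepresentative(relabel(e.graphlet, perm))
            orbits.append(CatalogOrbit(gid_counter, block, rep))
            gid_counter += 1
        entries.append(CatalogEntry(e.id, e.canonical, e.graphlet, tuple(orbits)))
    return GraphletCatalog(catalog.order, tuple(entries))


def classify_graphlet(g: Graphlet, catalog: GraphletCatalog) -> int:
    return catalog.classify_graphlet(g)


def classify_orbit(r: OrbitRepresentative, catalog: GraphletCatalog) -> int:
    return catalog.classify_orbit(r)
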