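"""Generation, merging and selection of the orbit-counting equation system.

Each equation starts from an orbit representative of order n-1 and a
nonempty proper subset of its vertices (the *required neighbors* of a new
vertex).  Adding a new vertex adjacent to the required neighbors plus every
subset of the remaining vertices produces the order-n representatives on the
left-hand side; each distinct orbit appears once, multiplied by the size of
the suborbit holding the new vertex.  The right-hand side counts, over all
instances of the starting representative anchored at the inspected vertex,
the common neighbors of the required set, minus the representative's own
vertices that already satisfy the requirement.

Equations whose left-hand sides list the same orbits describe symmetric ways
of building the same representatives and are merged: their right-hand sides
add, and a term's multiplicities add only when the two generation paths
produced edge-for-edge identical representatives (merely isomorphic ones
split the instances between them and keep the single factor).

Selection keeps, per left-hand-side *lowest orbit*, the first equation in
deterministic generation order, merging same-shaped latecomers.  Because an
added edge always increases an orbit's number, the retained system is
triangular: solved in descending lowest-orbit order it never meets an
unknown, and it covers every orbit except the complete graphlet's, which is
counted directly by clique enumeration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import _perm
from .errors import InputError, ConsistencyError
from .graphlets import OrbitRepresentative, extend_with_vertex, suborbits
from .naming import GraphletCatalog


@dataclass(frozen=True)
class RhsTerm:
    """One common-neighbor term: required subset of the start's vertices and
    the constant counting start vertices that already satisfy it."""

    subset: frozenset[int]
    minus: int

    def to_json(self) -> dict:
        return {"subset": sorted(self.subset), "minus": self.minus}


@dataclass(frozen=True)
class LhsTerm:
    orbit: int
    coeff: int
    #: concrete representative produced during generation; used by the merge
    #: rule, ignored by equality and serialization
    rep: OrbitRepresentative | None = field(default=None, compare=False)

    def to_json(self) -> dict:
        return {"orbit": self.orbit, "coeff": self.coeff}


@dataclass(frozen=True)
class Equation:
    order: int
    lhs: tuple[LhsTerm, ...]  # sorted by orbit id; first is the lowest orbit
    start_orbit: int | None
    rhs_terms: tuple[RhsTerm, ...]
    start_rep: OrbitRepresentative | None = field(default=None, compare=False)

    @property
    def lowest_orbit(self) -> int:
        return self.lhs[0].orbit

    @property
    def lhs_orbit_ids(self) -> tuple[int, ...]:
        return tuple(t.orbit for t in self.lhs)

    def to_json(self) -> dict:
        return {
            "order": self.order,
            "lowest_orbit": self.lowest_orbit,
            "lhs": [t.to_json() for t in self.lhs],
            "rhs": {
                "start_orbit": self.start_orbit,
                "terms": [t.to_json() for t in self.rhs_terms],
            },
        }

    @staticmethod
    def from_json(obj: dict, start_catalog: GraphletCatalog | None = None) -> "Equation":
        start_orbit = obj["rhs"]["start_orbit"]
        rep = None
        if start_catalog is not None and start_orbit is not None:
            for orb in start_catalog.orbit_representatives():
                if orb.global_id == start_orbit:
                    rep = orb.representative
                    break
        return Equation(
            order=obj["order"],
            lhs=tuple(LhsTerm(t["orbit"], t["coeff"]) for t in obj["lhs"]),
            start_orbit=start_orbit,
            rhs_terms=tuple(
                RhsTerm(frozenset(t["subset"]), t["minus"])
                for t in obj["rhs"]["terms"]
            ),
            start_rep=rep,
        )


def lhs_factor(r: OrbitRepresentative) -> int:
    """Multiplicity of a generated term: size of the newest vertex's suborbit.

    The vertices sharing a suborbit with the new vertex were interchangeable
    in the starting representative and carry a fixed ordering there; the new
    vertex may occupy any of the positions, so the term counts each instance
    once per suborbit member.
    """
    last = r.order - 1
    for block in suborbits(r):
        if last in block:
            return len(block)
    raise ConsistencyError("last vertex missing from suborbit partition")


def minus_term(start: OrbitRepresentative, neighbors) -> int:
    """Start vertices adjacent to every required neighbor.

    These satisfy the common-neighbor condition inside the representative
    itself and must be subtracted from the explored-graph count.  Members of
    the required set are never adjacent to themselves, so they drop out
    automatically.
    """
    nbrs = frozenset(neighbors)
    adj = start.graphlet.adjacency
    return sum(1 for v in range(start.order) if nbrs <= adj[v])


def _validate_neighbors(start: OrbitRepresentative, neighbors) -> frozenset[int]:
    nbrs = frozenset(neighbors)
    if not nbrs:
        raise InputError("required neighbor set must be nonempty")
    if not all(0 <= v < start.order for v in nbrs):
        raise InputError("neighbor index out of range")
    if len(nbrs) == start.order:
        raise InputError("required neighbors must be a proper subset")
    return nbrs


def generate_equation(
    start: OrbitRepresentative,
    neighbors,
    catalog: GraphletCatalog,
    start_catalog: GraphletCatalog | None = None,
) -> Equation:
    """Build one equation from a starting representative and required neighbors.

    ``catalog`` names the orbits of order ``start.order + 1``; the optional
    ``start_catalog`` fills in the start orbit's id.
    """
    nbrs = _validate_neighbors(start, neighbors)
    if catalog.order != start.order + 1:
        raise InputError("catalog order must be start order + 1")
    others = [v for v in range(start.order) if v not in nbrs]
    terms: dict[int, LhsTerm] = {}
    for bits in range(1 << len(others)):
        extra = frozenset(others[i] for i in range(len(others)) if bits >> i & 1)
        ext = extend_with_vertex(start, nbrs | extra)
        oid = catalog.classify_orbit(ext)
        if oid not in terms:
            terms[oid] = LhsTerm(oid, lhs_factor(ext), ext)
    lhs = tuple(terms[oid] for oid in sorted(terms))
    start_orbit = (
        start_catalog.classify_orbit(start) if start_catalog is not None else None
    )
    return Equation(
        order=catalog.order,
        lhs=lhs,
        start_orbit=start_orbit,
        rhs_terms=(RhsTerm(nbrs, minus_term(start, nbrs)),),
        start_rep=start,
    )


def merge(e1: Equation, e2: Equation) -> Equation:
    """Merge two equations with identical left-hand-side orbit lists.

    Right-hand sides concatenate (their sums add).  A term's coefficients add
    only when both generation paths produced the identical edge list -- the
    same concrete representative counted twice; isomorphic-but-distinct
    representatives partition the instances and keep the first coefficient.
    """
    if e1.lhs_orbit_ids != e2.lhs_orbit_ids:
        raise ConsistencyError("cannot merge equations with different orbit lists")
    if e1.start_orbit != e2.start_orbit:
        raise ConsistencyError("cannot merge equations with different start orbits")
    lhs = []
    for t1, t2 in zip(e1.lhs, e2.lhs):
        if (
            t1.rep is not None
            and t2.rep is not None
            and t1.rep.graphlet.edges == t2.rep.graphlet.edges
        ):
            lhs.append(LhsTerm(t1.orbit, t1.coeff + t2.coeff, t1.rep))
        else:
            lhs.append(t1)
    return Equation(
        order=e1.order,
        lhs=tuple(lhs),
        start_orbit=e1.start_orbit,
        rhs_terms=e1.rhs_terms + e2.rhs_terms,
        start_rep=e1.start_rep,
    )


@dataclass
class EquationSystem:
    """The retained, linearly independent system for one order.

    ``equations`` is keyed by lowest orbit id and covers every orbit of the
    order except the complete graphlet's.  ``n_generated`` counts every
    (representative, subset) pair visited; ``n_raw`` counts distinct
    equations after symmetric merging, i.e. subset classes under the start
    representatives' vertex symmetries.
    """

    order: int
    equations: dict[int, Equation]
    n_generated: int = 0
    n_raw: int = 0

    @property
    def n_retained(self) -> int:
        return len(self.equations)

    def sorted_keys_descending(self) -> list[int]:
        return sorted(self.equations, reverse=True)

    def to_json(self) -> dict:
        return {
            "order": self.order,
            "n_generated": self.n_generated,
            "n_raw": self.n_raw,
            "n_retained": self.n_retained,
            "equations": [self.equations[k].to_json() for k in sorted(self.equations)],
        }

    @staticmethod
    def from_json(obj: dict, start_catalog: GraphletCatalog | None = None) -> "EquationSystem":
        eqs = {}
        for e in obj["equations"]:
            eq = Equation.from_json(e, start_catalog)
            eqs[eq.lowest_orbit] = eq
        return EquationSystem(
            obj["order"], eqs, obj.get("n_generated", 0), obj.get("n_raw", 0)
        )


def _subset_class_key(subset: frozenset[int], auts) -> tuple[int, ...]:
    return min(tuple(sorted(p[v] for v in subset)) for p in auts)


def generate_system(
    catalog_n: GraphletCatalog, catalog_prev: GraphletCatalog
) -> EquationSystem:
    """Generate and select the equation system for ``catalog_n.order``.

    Iterates the order-(n-1) representatives in catalog order and required
    subsets in ascending bitmask order; per lowest-orbit key the first
    equation is kept and later same-shaped equations merge into it.
    """
    order = catalog_n.order
    if order < 3:
        raise InputError("equation systems start at order 3")
    if catalog_prev.order != order - 1:
        raise InputError("need the catalog of order n-1")
    equations: dict[int, Equation] = {}
    raw_classes: set[tuple[int, tuple[int, ...]]] = set()
    n_generated = 0
    k = order - 1
    for orb in catalog_prev.orbit_representatives():
        start = orb.representative
        auts = _perm.automorphism_perms(k, start.graphlet.code, fix_zero=True)
        for bits in range(1, (1 << k) - 1):
            subset = frozenset(v for v in range(k) if bits >> v & 1)
            n_generated += 1
            raw_classes.add((orb.global_id, _subset_class_key(subset, auts)))
            eq = generate_equation(start, subset, catalog_n, catalog_prev)
            key = eq.lowest_orbit
            held = equations.get(key)
            if held is None:
                equations[key] = eq
            elif (
                held.lhs_orbit_ids == eq.lhs_orbit_ids
                and held.start_orbit == eq.start_orbit
            ):
                equations[key] = merge(held, eq)
            # otherwise: linearly dependent duplicate, discarded
    return EquationSystem(order, equations, n_generated, len(raw_classes))


def check_system(system: EquationSystem, catalog_n: GraphletCatalog) -> None:
    """Raise unless the system is complete and triangular."""
    expected = set(range(catalog_n.n_orbits - 1))  # all but the complete graphlet
    if set(system.equations) != expected:
        raise ConsistencyError(
            "system keys do not cover every orbit except the complete graphlet's"
        )
    for key, eq in system.equations.items():
        ids = eq.lhs_orbit_ids
        if list(ids) != sorted(set(ids)) or ids[0] != key:
            raise ConsistencyError(f"equation {key}: malformed left-hand side")
        for oid in ids[1:]:
            if oid not in system.equations and oid != catalog_n.n_orbits - 1:
                raise ConsistencyError(
                    f"equation {key}: orbit {oid} is never solved"
                )


def render_equation(e: Equation, style: str = "text") -> str:
    """Human-readable rendering: plain text, LaTeX or the JSON schema."""
    if style == "json":
        return json.dumps(e.to_json(), sort_keys=True)
    if style not in ("text", "latex"):
        raise InputError(f"unknown render style: {style!r}")
    if style == "text":
        lhs = " + ".join(f"{t.coeff}*o{t.orbit}" for t in e.lhs)
        start = f"P{e.start_orbit}" if e.start_orbit is not None else "P"
        parts = []
        for t in e.rhs_terms:
            sub = ",".join(str(v) for v in sorted(t.subset))
            parts.append(f"c({{{sub}}})" + (f" - {t.minus}" if t.minus else ""))
        return f"{lhs} = sum over {start} of [ " + " + ".join(parts) + " ]"
    lhs = " + ".join(
        (f"{t.coeff} o_{{{t.orbit}}}" if t.coeff != 1 else f"o_{{{t.orbit}}}")
        for t in e.lhs
    )
    start = f"P_{{{e.start_orbit}}}" if e.start_orbit is not None else "P"
    parts = []
    for t in e.rhs_terms:
        sub = ",".join(str(v) for v in sorted(t.subset))
        parts.append(f"c(\\{{{sub}\\}})" + (f" - {t.minus}" if t.minus else ""))
    body = " + ".join(parts)
    if len(e.rhs_terms) > 1 or any(t.minus for t in e.rhs_terms):
        body = f"\\left[ {body} \\right]"
    return f"{lhs} = \\sum_{{{start}}} {body}"
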