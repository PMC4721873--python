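# Methods

## Model and definitions

A *graphlet* of order n is a connected simple graph on vertices 0..n−1,
considered up to isomorphism. An *explored graph* is the (larger) graph in
which graphlets are counted; an *instance* of a graphlet is a vertex subset
whose induced subgraph — all edges of the host between those vertices — is
isomorphic to it. The automorphism group of a graphlet partitions its
vertices into *orbits*; a vertex of the explored graph "touches" an orbit
once per instance in which it occupies that orbit's position.

An orbit is materialized as an *orbit representative*: its graphlet with
vertex 0 marked. Isomorphism between representatives must fix the mark, so
permutation machinery for representatives runs over the (n−1)! permutations
pinning vertex 0. Orbits of a representative's vertices under these
restricted automorphisms are called *suborbits*; they refine the graphlet's
orbits and encode which vertices look identical from the marked vertex.

## Canonical form and numbering

The strict lower triangle of the adjacency matrix, read row-major (rows
1..n−1, columns 0..r−1), gives an n(n−1)/2-bit string; the canonical string
is the lexicographic minimum over all n! relabelings, with '0' < '1'. Two
choices worth stating exactly:

* Bit layout and comparison are fixed as above so that results are
  bit-exact and adding an edge always flips a 0 to a 1 in every labeling,
  hence strictly increases the canonical string. This monotonicity makes
  graphlet ids (ranks in canonical-string order) compatible with edge
  addition, which the equation selection relies on; it is tested
  exhaustively through order 6.
* Representatives get the analogous canonical form with vertex 0 pinned:
  the minimum string over the (n−1)! mark-fixing relabelings, ties broken
  by the first permutation in `itertools.permutations` order. Two
  representatives denote the same orbit iff these strings (and orders)
  match.

Enumeration runs a binary counter over all 2^(n(n−1)/2) strings, decodes
each, keeps connected graphs and deduplicates by canonical string. Orbits
are numbered per order, starting at 0, grouped by graphlet id, and within a
graphlet by the smallest vertex label of the orbit in the canonical
labeling ("in the order their vertices first appear"). Per-order numbering
was chosen over a cumulative cross-order scheme because an equation system
only ever mixes orbits of a single order; totals (58 at order 5, 407 at
order 6) are unaffected by that choice. Each orbit's representative is
built by swapping the orbit's minimal vertex with label 0.

Internally strings are integers (first character = most significant bit),
so canonicalization is a minimum over bit-permuted integers. For orders ≤ 5
this runs in pure Python; for order 6 the 32,768-string × 720-permutation
product is vectorized with numpy (chunked gather + matrix–vector product),
taking a few seconds. Order 7 is accepted (the capability bound) but takes
hours with this exhaustive scheme; order 8 and beyond are refused, as
factorial canonicalization is no longer a sensible mechanism there.

## Equation generation

For a starting representative `start` of order n−1 and a required-neighbor
set S (nonempty proper subset of its vertices, the marked vertex allowed):

1. For every subset s of the remaining vertices (including the empty set),
   a new vertex adjacent to S ∪ s is appended (always receiving the highest
   index). Each distinct resulting orbit contributes one left-hand-side
   term; its coefficient is the size of the suborbit containing the new
   vertex (interchangeable vertices of the start carry a fixed ordering in
   instance matching, the new vertex does not, so each instance is produced
   once per member of that suborbit).
2. The right-hand side sums, over instances of `start` anchored at the
   inspected vertex, the common-neighbor count of the images of S minus the
   number of start vertices adjacent to all of S (those are counted by the
   explored-graph common-neighbor query but cannot serve as the new
   vertex).

Because the term with s = ∅ has the fewest edges, monotonicity makes it the
equation's *lowest orbit* — the unknown it will solve.

**Merging.** Two equations generated from the same start with identical
left-hand-side orbit lists describe symmetric routes to the same outcomes
and merge: right-hand sides concatenate, and a term's coefficients add
exactly when the two routes produced edge-for-edge identical
representatives (the same concrete outcome counted twice). Merely
isomorphic outcomes split the instances between the routes and keep the
single factor. This rule reproduces the hand-derived coefficient pairs at
order 4, and its ultimate arbiter is the exact solver-versus-oracle
agreement on random graphs at orders 4–6, which holds. A consequence worth
noting: merged non-leading terms can exceed the per-route suborbit bound
(an order-4 equation legitimately carries 6·o_K4 after two routes each
contribute factor 3); only the leading coefficient is always a plain
suborbit size.

**Selection.** Iterating representatives in catalog order and subsets in
ascending bitmask order, the first equation per lowest-orbit key is kept
and later same-shaped (same lhs list, same start orbit) equations merge
into it; other collisions are linearly dependent and discarded. Merging is
additionally conditioned on equal start orbits — a same-shaped equation
from a different start is discarded rather than merged, since the kept
equation is already valid once its own symmetric partners merged (no such
collision is observed through order 6). The retained system has exactly one
equation per orbit except the complete graphlet's single orbit, and is
triangular: solving in descending key order never meets an unknown.

Two statistics are reported because the generation count is ambiguous in
principle: `n_generated` counts every (representative, subset) pair (154 at
order 5), and `n_raw` counts distinct equations after symmetric merging,
computed as subset classes under the start's mark-fixing automorphisms (114
at order 5, with 57 retained).

## Counting

* `brute_force_counts` (the oracle) walks every order-n vertex subset,
  skips disconnected induced subgraphs, and classifies each member vertex's
  orbit through the canonical machinery, cached per induced edge pattern
  (at most 2^(n(n−1)/2) patterns, so the cache saturates quickly).
* `solve_counts` seeds the complete graphlet's orbit by clique enumeration
  (recursive extension over index-sorted candidates), then back-substitutes
  the equations in descending lowest-orbit order. Instance matching uses
  backtracking over a connectivity-respecting placement order with full
  induced (edge and non-edge) checks, keeping one mapping per mark-fixing
  automorphism class — the class member whose image tuple is smallest in
  the graph's vertex order. Every leading-coefficient division must be
  exact; a remainder raises immediately, since it can only mean a defective
  equation.

Vertex identifiers are arbitrary hashable values kept in first-seen order,
which makes all outputs deterministic and byte-stable for a fixed input.

## Random-graph fixtures

`random_graph(n, p, seed)` draws each of the C(n,2) possible edges
independently with probability p from a `random.Random(seed)` stream in a
fixed order — a seeded Erdős–Rényi G(n, p) generator. It emulates the one
property the correctness checks need: arbitrary, reproducible mixtures of
sparse and dense neighborhoods. It does not emulate degree heterogeneity,
clustering or modularity of real biological networks; passing tests assert
the combinatorial identity between the two counters on arbitrary graphs,
not any statistical claim about real data. The verification sweep uses
15–25-vertex graphs at p ∈ {0.2, 0.4, 0.6} for orders 4 and 5 (21 graphs
per order) and ≤ 14-vertex graphs at order 6 — sizes at which the
brute-force oracle stays fast while covering sparse through dense regimes.

## Degenerate inputs and edge cases

* The single-vertex graph is connected; orders 1 and 2 have one graphlet
  and one orbit each. Equation systems start at order 3 (built from the
  single order-2 representative); smaller requests are input errors.
* Disconnected graphs are representable via a relaxed constructor for
  intermediate machinery, but every enumeration, classification and
  equation API rejects them.
* Duplicate edges in an input edge list warn and collapse by default, or
  raise under `--strict`; self-loops always raise, with line numbers.
* An isolated explored-graph vertex yields an all-zero count row through
  both counters.

## Known limitations

* Everything is exponential in the graphlet order by design; order 7 is the
  hard capability bound and already impractical for enumeration. The
  counters are reference implementations for validation and small studies,
  not competitors to optimized production counters.
* Orbit ids are this package's canonical numbering; the historical
  hand-assigned numbering for orders ≤ 5 is not reproduced (the
  correspondence lives only in drawings and is not needed by the
  machinery).
* Graphlet-degree-distribution aggregation and network-comparison metrics
  on top of the count tables are out of scope.
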