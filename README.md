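# orbiteq

Order-independent machinery for graphlet analysis: canonical enumeration and
naming of graphlets and orbits of any (small) order, automatic generation of
the linearly independent system of combinatorial orbit-counting equations,
and a reference counter that measures, for every vertex of an explored
graph, how many times it touches each orbit.

## Why

Graphlets — small connected simple graphs considered up to isomorphism — are
a standard way to characterize local structure in biological and other
networks. For each graphlet, the vertices split into *orbits* (equivalence
classes under the automorphism group), and the graphlet degree distribution
of an orbit records how many vertices of a network touch it k times.
Counting orbits directly by enumerating induced subgraphs is expensive.
The combinatorial-equation approach instead counts only instances of
order-(n−1) graphlets plus common neighbors of vertex sets, and recovers all
order-n orbit counts by solving a triangular system of linear equations with
integer coefficients. Historically these systems were derived by hand for
orders 4 and 5 only; this package derives them automatically for any order,
together with a naming scheme that extends mechanically beyond order 5.

## The core machinery

* **Canonical naming.** A graphlet's strict lower-triangular adjacency bits,
  read row-major, form a string; the lexicographic minimum over all n!
  relabelings is a complete isomorphism invariant. Because an added edge
  only ever flips a 0 to a 1, sorting canonical strings orders graphlets
  compatibly with edge addition — the property the equation selection needs.
  Graphlets of an order are numbered by that sort; orbits are numbered in
  the order their vertices first appear in the canonical labeling.
* **Orbit representatives and suborbits.** An orbit is represented as its
  graphlet with one marked vertex (vertex 0), compared under permutations
  that never move the mark. Automorphisms that fix the mark partition the
  vertices into *suborbits*, which supply the multiplicities of the
  equations.
* **Equation generation.** From each order-(n−1) representative `G(x)` and
  each nonempty proper vertex subset S (the required neighbors of a new
  vertex), expanding the new vertex's optional adjacencies yields

      Σ_i  f_i · o_i  =  Σ_{instances of G(x) at x}  ( c(S) − m ),

  where `o_i` are order-n orbit counts at the inspected vertex, `f_i` is the
  size of the suborbit holding the new vertex, `c(S)` counts common
  neighbors of the images of S in the explored graph, and `m` counts the
  representative's own vertices already adjacent to all of S. Symmetric
  generation routes merge: right-hand sides add, and coefficients of
  edge-identical outcomes add. Keeping one equation per *lowest* orbit
  yields a triangular system covering every orbit except the complete
  graphlet's, which is counted directly by clique enumeration.
* **Two counters.** `solve_counts` evaluates the system per vertex by
  back-substitution in descending orbit order (every division must be
  exact); `brute_force_counts` classifies every connected induced subgraph
  directly and serves as the oracle. The package's primary correctness
  statement is their exact, per-vertex, per-orbit agreement.

## Worked example

Enumerate, generate equations, and count on a 5-vertex toy graph
(`a b / a c / a d / b c / c d / d e` as an edge list):

```
$ orbiteq equations --order 4 --raw-count
generated: 18
after symmetric merging: 14
retained: 10

$ orbiteq count --graph toy.txt --order 4 --method equations
vertex	o0	o1	o2	o3	o4	o5	o6	o7	o8	o9	o10
a	0	0	0	1	0	1	0	0	0	1	0
b	0	0	2	0	0	0	0	0	1	0	0
c	0	0	0	1	0	1	0	0	0	1	0
d	0	0	0	2	0	0	1	0	1	0	0
e	0	0	2	0	1	0	0	0	0	0	0
```

Columns are the 11 order-4 orbit ids in canonical numbering (o10 is the
complete graphlet K4's single orbit). Row `a` says vertex *a* touches
orbit 3 once, orbit 5 once and orbit 9 once: it sits in one 4-path, one paw
and one diamond among the graph's connected induced 4-vertex subgraphs.
Running with `--method brute` produces the identical table, and

```
$ orbiteq verify --order 4 --graphs 20 --nodes 18 --p 0.4 --seed 1
verified 20 graphs at order 4: exact agreement
```

checks that agreement systematically on seeded random graphs (exit code 4
on any mismatch).

The first retained order-4 equation renders as

```
$ orbiteq equations --order 4 | head -1
2*o0 + 2*o4 + 1*o5 + 2*o8 = sum over P0 of [ c({2}) - 2 ]
```

read: twice the count of orbit 0 plus … equals, summed over all instances
of order-3 orbit representative 0 anchored at the vertex, the number of
common neighbors of the image of representative vertex 2, minus the two
representative vertices that already satisfy the requirement.

## Scope and limits

Isomorphism is decided by exhaustive permutation (n!, or (n−1)! with the
mark pinned), as befits the working range: enumeration is instantaneous
through order 5, takes seconds at order 6, and is accepted but impractical
at order 7 (the hard ceiling). The counters are reference implementations
aimed at exactness on graphs of tens of vertices, not performance-engineered
production counters. See `docs/methods.md` for the model details, numerical
choices and limitations.
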