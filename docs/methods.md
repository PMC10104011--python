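# Methods

## Graph substrate

A signed directed interaction network (TSV edge list) is collapsed onto an
undirected simple graph before any tree search: edge directions and signs
carry no information a spanning tree can use, self-loops are dropped, and
reciprocal/parallel directed edges merge into one undirected edge.  When
interactions carry probabilities, the merged probability follows a
configurable policy — `max` by default (keeps the strongest evidence that
the interaction exists), `mean` and `noisy-or` as alternatives — and each
edge gets weight `w = 1 − p`.  Undirected edges receive stable 1-based
indices in first-appearance order, so a chromosome (a vector of edge
indices) means the same tree in every run and process.  Disconnected input
is a hard error at the optimization entry points: no spanning tree exists.

The distance objective is stored as the ordered-pair sum
`Σ_{i≠j} d(v_i, v_j)` — twice the unordered (Wiener-index) sum — computed
by breadth-first search from every node of the candidate tree.  Closed
forms anchor the tests: the unordered sum is `n(n²−1)/6` for a path and
`(n−1)²` for a star on `n` nodes.

## Genetic search for (M)DSTs

Minimum routing-cost spanning trees are NP-hard, hence a restarted genetic
algorithm:

* **Genotype → phenotype.**  A chromosome is a fixed-length vector of `K`
  distinct edge indices; Kruskal extracts a spanning tree by greedy
  cycle-free addition in subset order.  `K` defaults to
  `min(M, ⌈1.5 (N−1)⌉)`: the slack lets extraction choose among edges,
  which empirically speeds convergence.
* **Feasibility repair** (deterministic): while the chromosome's subgraph
  is disconnected, append the lowest-index graph edge joining two
  components; then evict the highest-index cycle-closing edges to restore
  length `K`.  Every individual is therefore always feasible; no penalty
  tuning.
* **Operators.**  Tournament selection (size 3), uniform index crossover
  with duplicate repair from the parents' gene pool, single-index point
  mutation, elitism of 2.
* **Archive.**  Every feasible evaluated tree attaining the best objective
  seen across all restarts is archived, deduplicated on its sorted edge-set
  tuple.  This mirrors the practice of reporting *all* co-optimal trees:
  the hub statistic averages over the archive.
* **Budget.**  Defaults are population 80, up to 250 generations with an
  early stop after 25 generations without improvement, 20 restarts.  These
  sizes solve desk-scale instances (N ≤ 35) in seconds to minutes on one
  CPU and, on random graphs small enough for exhaustive enumeration
  (N ≤ 9), recover the exact optimum in ≥ 95% of instances.  All knobs are
  exposed in `GAConfig`; runs are bit-reproducible from the seed (one
  independent deterministic stream per restart).

### Multi-objective handling (MDST)

The second objective sums `w_i` over the edges of the extracted tree `h*`,
not over the whole chromosome: slack genes never enter the reported tree,
and counting them would add spurious weight (the literal chromosome sum is
available behind `weight_on_chromosome`).  Because the reference analyses
report a single optimal objective value rather than a Pareto front, the
default scalarization is lexicographic — distance strictly first, weight as
tie-break — implemented as `scalar = distance · (1 + Σw) + weight`, where
`Σw` (the total graph weight) bounds any achievable weight difference so
one distance step always dominates.  A plain weighted sum
(`α·distance + weight`) is available.  A full Pareto archive is out of
scope.

Whether Kruskal extraction itself should order edges by weight was a
genuinely open design point.  Both variants are implemented; the default is
**subset-order (unweighted) extraction**, because weight-ordered extraction
measurably breaks the search: a light slack edge displaces a heavier edge
of the intended tree during extraction, making many minimum-distance trees
unreachable from any chromosome with slack, and even with `K = N−1`
(genotype ≡ tree) the search converges poorly on 12-node instances.  With
subset-order extraction the weight objective still steers selection through
the scalarization, and lexicographic agreement with brute force is exact on
all tested small graphs.  `weighted_kruskal=True` restores weight-ordered
extraction (and then defaults `K` to `N−1` to preserve reachability).

### Oracles

Two independent ground-truth routes guard the GA: exhaustive spanning-tree
enumeration (via networkx's spanning-tree iterator, refused above a
configurable count cap) evaluated with the same objectives, and the
matrix-tree (Kirchhoff) determinant for counting.  The GA can never beat
the enumerated optimum — any violation would expose an objective bug.

## Hub statistic

The hub profile is each node's mean tree degree across the archive; the
averages always sum to `2(N−1)`.  "Hub" is operationalized as top-k or
threshold on this average (descending, alphabetical tie-break) — the
underlying analyses identify hubs visually from the degree profile, so no
canonical numeric cutoff exists.

## Asynchronous probabilistic Boolean simulation

Rules are per-node probability tables over regulator-state combinations,
with the **first listed regulator as the most significant bit** of the
table index (bit-exact, documented, tested).  One iteration picks a node
uniformly at random; a clamped node is forced to its clamp value (the pick
still consumes the iteration, keeping iteration-count semantics uniform —
clamping holds a node, it does not remove it from the update scheme); any
other node is resampled Bernoulli from its table entry.  Consecutive states
differ in at most one position.

Convergence is first exact match to any state in the target set; a
stability window is deliberately absent by default because stochastic rules
can legitimately leave a target state.  The default iteration cap is
5×10⁵, comfortably above the observed order of 10⁵ iterations for
clamped transitions at full network scale.  Ensembles use per-run seeds
`base_seed + i` and an optional per-run callback for incremental
persistence.

## Distance and pattern analytics

With `A(v1, v2)` the LCS length of the two binary state vectors (classic
dynamic program), the default distance is the metric form
`2m − 2·A(v1, v2)`: zero exactly on identical vectors, symmetric, triangle
inequality (property-tested on random triples).  The single-count variant
`A(v1,v1) + A(v2,v2) − A(v1,v2)` is kept as `form="as-printed"` for
fidelity with the formula as sometimes typeset; it equals `m` on identical
vectors and is therefore unsuitable for reading convergence as
distance → 0, which is why it is not the default.  Hamming distance is a
drop-in alternative.  Distance to a target *set* is the minimum over the
set.

Patterns are maximal runs of consecutive same-sign *change events*
(iterations whose update changed the distance).  Flat iterations neither
extend nor break a run — the change-event convention makes the per-TF
statistics well-defined and conservation-checkable: per-direction frequency
totals equal the change-event totals, directions strictly alternate, and a
hitting trajectory's final change event is decreasing.  A pattern's
initiation state is the network state immediately before its first event;
the fraction of decreasing patterns in which a TF is ON at initiation flags
TFs that push toward the target.

## Synthetic data

The generators emulate the class of inputs the pipeline consumes in the
wild (curated TF networks with expression-derived interaction
probabilities and fitted probabilistic rules), not any particular dataset:

* **Planted-hub networks**: hubs wired to all other nodes (attachment
  probability 1 by default), independent peripheral noise edges
  (probability 0.1), random directions and signs, edge probabilities from
  Beta(5, 2) — skewed high, as expected for literature-curated
  interactions.  Connected by construction; deterministic per seed.
* **Rules from attractors**: regulator combinations observed in a
  designated attractor reproduce the attractor value, softened toward 0.5
  by a noise level `ε ∈ [0, 0.5]`; unobserved combinations get
  sign-majority logic (activators ON minus inhibitors ON; tie → 0.5).
  Conflicting attractors are an error naming the node — silently softening
  an inconsistency would invalidate every transition test built on the
  rules.  At `ε = 0` each attractor is a verified fixed point.
* **Toy fixture**: a fixed 8-node, 14-edge network with hubs H1/H2, a
  pathway intermediate A and a repressor R; resting state S0 (all OFF,
  R ON) and target S1 (all ON, R OFF) are both fixed points, and the clamp
  set {H1=ON, A=ON} makes S1 reachable from S0 (empirically ~25 iterations
  on average, hit rate 100/100 seeds).  Byte-identical across calls.

What passing on these generators does **not** show: real TF networks are
not planted stars (hub recovery on them is a calibration of the pipeline's
plumbing, not a biological claim), real fitted rules are not derived from
two clean attractors, and real transition times depend on rule noise that
the fixture fixes at ε = 0 (ε = 0.15 is used where both distance
directions must occur).

## Problem sizes used in the checks

Oracle-equivalence checks run the default-budget GA against exhaustive
enumeration on 50 random connected graphs (N ≤ 9 unweighted, N ≤ 8
weighted); hub recovery uses 100 ten-node planted-hub instances with a
reduced budget (population 60, 120 generations, 3 restarts) — the planted
star is an easy instance and the reduced budget keeps the 100-run sweep
fast; simulator statistics use 10⁵ iterations (stationary fraction) and
10⁴ runs (hitting time); metric axioms use 10⁴ random triples with
m ≤ 20.  The acceptance script scales the graph sweeps to 30 instances and
hub recovery to 60 runs.

## Known limitations

* No directed-spanning (arborescence) variant: the analysis deliberately
  strips directions; adding them changes the constraint structure of the
  optimization.
* No Pareto front for the MDST problem; scalarizations only.
* Archive sizes are not comparable across implementations or budgets — how
  many co-optimal trees a run collects depends on population bookkeeping,
  not only on the optimum.
* The GA is a metaheuristic: beyond the exhaustively checkable sizes its
  optima are best-found, not certified.
* No rule fitting from expression data: rule tables are consumed, not
  inferred.  No synchronous or ODE dynamics.
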