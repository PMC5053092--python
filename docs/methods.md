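# Methods

## Problem

Given an undirected simple graph `G = (V, E)` — in practice a
protein–protein interaction (PPI) network — a target motif size `μ` and a
frequency threshold `α`, find every pattern (graph topology) of size `μ`
whose *disjoint* frequency in `G` is at least `α`.  Three frequency
notions are involved:

* `F1(M)` — the number of all embeddings of pattern `M` (subgraphs of `G`
  isomorphic to `M`, identified by their edge sets);
* `F2(M)` — the size of a largest set of pairwise **edge-disjoint**
  embeddings;
* `F3(M)` — the same with **node-disjoint** embeddings.

`F1` is not monotone under pattern growth (it can increase when edges are
added), which breaks any early-stopping search.  `F2` and `F3` are
downward closed: if `M ⊂ M̄` then `F2(M) ≥ F2(M̄)` — delete the extra
edges from each disjoint embedding of `M̄` and you obtain as many disjoint
embeddings of `M`.  The discovery algorithm relies on this: a pattern
whose disjoint frequency falls below `α` can be pruned for good.

## Discovery by joining

Every connected graph with two or three edges is one of four *basic
building patterns*: the 2-edge path (M1), the triangle (M2), the 3-star
(M3) and the 3-edge path (M4).  Any connected pattern with `k+1` edges can
be written as the union of a `k`-edge (or `k−1`-edge) subpattern and one
basic pattern overlapping it in at least one edge, so iterated joining of
current motif instances with basic-pattern instances can reach any
topology.  The search:

1. enumerate all embeddings of M1–M4 (`Σ_v C(d(v),2)` 2-paths,
   `Σ_v C(d(v),3)` stars, triangles once per sorted node triple, 3-paths
   once from their unique middle edge);
2. extract each basic pattern's disjoint embedding set and drop basic
   patterns below `α`;
3. repeatedly join every disjoint instance of every current pattern with
   the basic-pattern instances (two instances join iff they share an edge
   and the union strictly grows the motif instance), classify the products
   into isomorphism classes, deduplicate instances by canonical edge-set
   key, recount disjoint frequencies, and prune below `α`;
4. harvest classes that reach the target size; stop when nothing grows.

Instance lists are *not* guaranteed complete (the join only sees instances
of the chosen source sets), so reported frequencies are lower bounds on
the exact disjoint frequency; reported patterns always exist in `G` by
construction.  `join_source="all"` joins against the basic patterns' full
embedding lists instead of their disjoint sets, trading time for recall;
the worked examples in the tests that need exact instance recovery use it.

Size accounting (`size_mode`) supports both conventions in use: `nodes`
(default, the problem definition) and `edges` (the convention of
edge-growth miners).  In node mode a class that reaches `μ` nodes stays
joinable — further joins can add edges without adding nodes — until it
reaches the `C(μ,2)` edge bound.

## Disjoint counting (greedy MIS)

The disjoint frequency of a pattern is the independence number of its
*overlap graph* (vertices = embeddings, edges = overlapping pairs).
Exact maximum independent set being NP-hard, a minimum-degree greedy is
used: accept the embedding with the fewest overlaps, discard its
neighbours, repeat.  Ties are always broken by the canonical embedding key,
so runs are bit-reproducible.  The greedy output is verified on every call
to be an independent and maximal set (a cheap linear certificate).

For derived patterns the overlap graph is built explicitly (their
embedding lists are short).  For the four basic patterns — whose
embedding lists are the largest by far — the overlap counts are computed
*algebraically* and the greedy becomes a single accept/reject sweep in
ascending overlap-count order against a running used-edge (F2) or
used-node (F3) set; overlap adjacency is never materialised.  The two
textual descriptions of the processing order disagree in places
(minimum-degree-first selection vs a sort in "decreasing order"); this
implementation processes ascending (fewest overlaps first) in both
heuristics, which is the order the greedy selection rule itself implies.

### Algebraic overlap counts

For an M1 embedding `{(a,c),(b,c)}` with middle node `c`, the number of
other 2-paths sharing an edge is the closed form

    2(d(c) − 2) + (d(a) − 1) + (d(b) − 1) = 2 d(c) + d(a) + d(b) − 6.

The remaining edge-overlap (F2) counts are inclusion–exclusion over the
embedding's 2–3 edges, with all terms local:

* per-edge embedding counts use degrees and the per-edge common-neighbour
  count `c(u,v) = |N(u) ∩ N(v)|` (e.g. a triangle's edge `(u,v)` lies in
  `c(u,v)` triangles; an edge is the middle of
  `(d(u)−1)(d(v)−1) − c(u,v)` 3-paths);
* multi-edge terms collapse to degree expressions plus adjacency
  indicators (e.g. exactly `1 + A(u,b) + A(a,v) + A(a,b)` 3-paths contain
  both end edges of the 3-path `a–u–v–b`).

Node-overlap (F3) counts are inclusion–exclusion over the embedding's 3–4
nodes.  The singleton terms (embeddings through one node) have per-node
closed forms; the higher-order terms (embeddings through ≥ 2 fixed nodes)
are evaluated by a constrained placement counter: the fixed nodes are
assigned to template positions and the remaining positions are filled from
intersections of host neighbourhoods.  These terms are strongly
constrained and heavily shared between embeddings around hubs, so they are
memoised on the graph.  No pairwise embedding comparison occurs anywhere
on this path.  All overlap formulas are validated against an O(k²)
brute-force oracle in the test suite (all four patterns, both measures, 50
random scale-free graphs), and a `brute_force=True` switch keeps the
oracle path available for debugging.

## Isomorphism filtering

Products of joins are classified with a filter cascade before any exact
test:

1. **degree vector** — sorted within-pattern degrees; different vectors
   prove non-isomorphism.  On 1000 generated pairs of non-isomorphic
   Barabási–Albert graphs with matched node and edge counts, this filter
   alone separates well above 85 % of pairs (recomputed by
   `scripts/acceptance.py`).
2. **nodes vector** — sorted per-node labels
   `label(v_i) = Σ_{j∈V} 2^(x − x_ij − d(v_j))`, with `x` the pattern
   diameter and `x_ij` the shortest-path length; the `j = i` self term
   (with `x_ii = 0`) is included, reading the sum literally over all of
   `V`.  Either inclusion choice yields a valid isomorphism invariant;
   this one is documented and frozen.  Labels are dyadic rationals;
   comparisons use an absolute tolerance of 1e−9 after sorting purely to
   guard accumulated float error.
3. survivors get an exact backtracking bijection search (descending-degree
   ordering, degree-compatibility and adjacency-consistency pruning) —
   adequate because patterns are small (tens of edges at most).

Patterns are compared as bare edge sets (non-induced semantics): a 3-edge
path whose endpoints happen to be adjacent in the host is still a 3-edge
path.  No true canonical form is computed; the reported "pattern edges"
are a stable BFS-relabelled representative, deterministic for a given run
but not canonical across isomorphic inputs.

## Significance

Two z-scores for the most abundant motif of size `μ`:

* **within-graph**: `z = (x₁ − x̄)/σ` over the frequencies of all motifs
  of the same size in the same graph (found with `α = 1`);
* **versus a null ensemble**: `z = (x − x̄)/σ` where the `x_i` are top
  frequencies in `n` degree-preserving randomizations of `G`.  Defaults:
  `n = 100` replicas, each produced by `10·|E|` *successful* double-edge
  swaps — two edges `(v₁,v₂), (u₁,u₂)` picked uniformly at random are
  rewired to `(v₁,u₂), (u₁,v₂)`; proposals creating self-loops or
  parallel edges are rejected, retried and not counted, with a cap of
  `100·|E|` proposals (a warning is emitted on the rare stall, e.g. an
  isolated triangle, and the current state returned).

`σ` is the sample standard deviation (n−1 denominator; the convention had
to be fixed somewhere and is recorded here).  `σ = 0` yields an explicit
"undefined" flag rather than a value.  `|z| > 2` is labelled significant.
Replica RNG streams are derived from `(seed, replica index)` so ensembles
are reproducible and order-independent.

## Synthetic data

The generator produces Barabási–Albert preferential-attachment graphs:
a seed clique of `density + 1` nodes, then each arriving node attaches
`density` edges proportionally to current degree (no parallel edges), so
`|E| = C(density+1, 2) + (n − density − 1)·density`.  `density = 2`
(mean degree ≈ 4) is the default study condition; densities 1–4 cover the
edges-per-node range of typical PPI networks.  BA graphs reproduce the
heavy-tailed degree distribution of PPI data but none of its biology —
no date/party hub distinction, no complex co-membership, no noise model
of spurious interactions — so green tests certify algorithmic
correctness on scale-free topology, not biological conclusions.

The filter-rate experiment draws pairs of independent BA graphs with
matched `n` (uniform in 20–60) and density 2 (hence matched `|E|`),
rejecting the rare isomorphic pair (degree-sequence precheck, then VF2).
These parameters were not published with the original experiment; they
are this package's fixed, recorded choice.

## Numerical and scale choices

* All tie-breaks (greedy selection, algebraic sweep, report ordering) use
  lexicographic canonical keys; identical config + seed ⇒ byte-identical
  output.
* Component preprocessing removes components with fewer than `μ` nodes
  (node mode) or fewer than the minimum node count a `μ`-edge connected
  graph needs (edge mode).
* The join loop is capped at `C(μ,2) + 2` iterations (node mode) /
  `μ + 2` (edge mode) as a safety bound; each productive join adds at
  least one edge, so the cap is never binding on sane inputs.
* Test oracles run at deliberately small scale: brute-force overlap
  comparison on 50 BA graphs with `n ∈ [12, 40]`, exact MIS (via maximum
  clique on the complement) only on instances with ≤ 18 embeddings, and
  downward-closure checks on sparse graphs with `n ≤ 25`.  These sizes
  exercise every code path while keeping the oracle (exponential or
  quadratic) honest and fast.

## Known limitations

* Completeness of instance lists is heuristic (see above); frequencies
  are lower bounds.  Worked examples that require full instance recovery
  (e.g. all three embeddings of the triangle-with-pendant pattern in the
  toy graph) need `join_source="all"`.
* The exact-MIS solver exists only as a test oracle; production counting
  is greedy and can undershoot the true independence number.
* Directed and weighted graphs, node/edge labels, and approximate or
  sampled counting are out of scope.
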