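# motifdisc

Disjoint network-motif discovery for biological networks.

Motif analysis asks which small subgraph topologies recur in an
interaction network more often than chance.  Counting *all* embeddings of
a pattern (the classical `F1` frequency) inflates counts — one hub edge
can sit in thousands of embeddings — and `F1` is not monotone as patterns
grow, so no search can prune early.  `motifdisc` instead counts
**edge-disjoint** (`F2`) or **node-disjoint** (`F3`) embeddings: the size
of a maximum independent set in the pattern's overlap graph.  These
measures are *downward closed* (`M ⊂ M̄ ⇒ F2(M) ≥ F2(M̄)`), which makes
large-motif discovery tractable: given a graph `G`, a motif size `μ` and a
frequency threshold `α`, the tool finds all patterns of size `μ` with
disjoint frequency ≥ `α` by iteratively joining motif instances with the
four basic building patterns (the 2-edge path, triangle, 3-star and
3-edge path — jointly exhaustive for 2–3 edges and sufficient to compose
any larger topology).  Candidate classification is accelerated by
degree-vector and distance/degree-label filters ahead of the exact
isomorphism test; the basic patterns' overlap counts are computed in
closed form from host degrees (e.g. `2d(c) + d(a) + d(b) − 6` for a
2-path `a–c–b`) rather than by pairwise comparisons.  Motif abundance can
be scored against degree-preserving null models (double-edge-swap
randomization, z-scores).

Intended users: systems-biology and network-analysis groups mining
protein–protein interaction (or other undirected biological) networks for
recurring large motifs.

## Worked example

The seven-node toy network with two triangles bridged by a hub:

```
# fig1.el — triangle a,b,c; bridge b-e; pendant e-d; triangle e,f,g
a b
a c
b c
b e
e d
e f
f g
e g
```

Find all 4-edge motifs with edge-disjoint frequency at least 2:

```sh
$ motifdisc find-motifs -g fig1.el --size 4 --size-mode edges --alpha 2 --measure F2
pattern_id  n_nodes  n_edges  frequency  pattern_edges
P0          4        4        2          0-1;0-2;0-3;1-2
```

`P0` is the triangle with a pendant edge (node 0 touches all others;
0–1–2 close a triangle).  Its frequency is 2: the network contains three
embeddings of this pattern, but only two of them are edge-disjoint — the
third reuses the bridge edge — so the honest disjoint count is 2.

Count one specific pattern's three frequencies (`pat.el` holds the same
triangle-with-pendant topology):

```sh
$ motifdisc count-pattern -g fig1.el -p pat.el
{"F1": 3, "F2": 2, "F3": 1}
```

All embeddings: 3.  Edge-disjoint: 2.  Node-disjoint: only 1, because
every pair of embeddings shares at least one node.

Score the most abundant 4-edge motif against the other motifs of its
size:

```sh
$ motifdisc significance -g fig1.el --size 4 --size-mode edges --join-source all --mode within
{ ... "top_frequency": 2, "mean": 1.25, "sd": 0.5, "z": 1.5, "significant": false ... }
```

z = 1.5 < 2: on this toy graph the top motif is not significantly more
abundant than its size peers.  `--mode random` scores against 100
degree-preserving randomizations instead (`--n-random`, `--swaps`
configurable); `simulate ba` generates Barabási–Albert benchmark graphs.

## Library use

```python
from motifdisc import DiscoveryConfig, find_motifs, fig1_graph

report = find_motifs(fig1_graph(),
                     DiscoveryConfig(mu=4, alpha=2, size_mode="edges"))
for rec in report.records:
    print(rec.pattern_edges, rec.frequency)
```

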