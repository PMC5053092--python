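"""The four basic building patterns and their algebraic overlap counts.

Every connected graph with two or three edges is isomorphic to one of

* M1 — the 2-edge path,
* M2 — the triangle,
* M3 — the 3-star,
* M4 — the 3-edge path,

and every larger connected pattern can be obtained by joining a smaller
pattern with one of these four.  The discovery algorithm therefore seeds
its search with the full embedding lists of M1-M4.

Because the basic patterns typically have far more embeddings than any
derived pattern, their overlap-graph degrees (the number of other
embeddings an embedding overlaps) are computed *algebraically* from host
degrees, common-neighbour counts, and one-hop neighbour sums — never by
pairwise embedding comparisons.  The M1 edge-overlap count is the closed
form 2 d(c) + d(a) + d(b) - 6 (middle node c, ends a and b); the remaining
cases are inclusion-exclusion over the shared edges (F2) or shared nodes
(F3) of the embedding.
"""

from __future__ import annotations

import enum
from itertools import combinations, permutations
from math import comb
from typing import Iterable, Sequence

from .graph_core import Embedding, NetworkGraph, NodeId, edge_key


class Measure(str, enum.Enum):
    """Disjointness measure: F2 = edge-disjoint, F3 = node-disjoint."""

    F2 = "F2"
    F3 = "F3"


class BasicPattern(str, enum.Enum):
    M1 = "M1"  # 2-edge path
    M2 = "M2"  # triangle
    M3 = "M3"  # 3-star
    M4 = "M4"  # 3-edge path

    @property
    def template_edges(self) -> tuple[tuple[int, int], ...]:
        return _TEMPLATES[self]

    @property
    def n_edges(self) -> int:
        return len(_TEMPLATES[self])

    @property
    def degree_vector(self) -> tuple[int, ...]:
        return _TEMPLATE_DEGSEQ[self]

    @property
    def automorphisms(self) -> int:
        return _TEMPLATE_AUT[self]


_TEMPLATES: dict[BasicPattern, tuple[tuple[int, int], ...]] = {
    BasicPattern.M1: ((0, 1), (1, 2)),
    BasicPattern.M2: ((0, 1), (1, 2), (0, 2)),
    BasicPattern.M3: ((0, 1), (0, 2), (0, 3)),
    BasicPattern.M4: ((0, 1), (1, 2), (2, 3)),
}
_TEMPLATE_DEGSEQ = {
    BasicPattern.M1: (1, 1, 2),
    BasicPattern.M2: (2, 2, 2),
    BasicPattern.M3: (1, 1, 1, 3),
    BasicPattern.M4: (1, 1, 2, 2),
}
_TEMPLATE_AUT = {
    BasicPattern.M1: 2,   # reflection
    BasicPattern.M2: 6,   # S3
    BasicPattern.M3: 6,   # leaf permutations
    BasicPattern.M4: 2,   # reflection
}


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_basic(g: NetworkGraph, pid: BasicPattern) -> list[Embedding]:
    """All distinct embeddings of ``pid`` in ``g``, each exactly once.

    M1/M3 are enumerated per centre node (inherently unique); each triangle
    is emitted once via its lexicographically sorted node triple; each
    3-edge path once from its unique middle edge.
    """
    out: list[Embedding] = []
    if pid is BasicPattern.M1:
        for v in sorted(g.nodes):
            for a, b in combinations(sorted(g.neighbors(v)), 2):
                out.append(Embedding([(a, v), (v, b)]))
    elif pid is BasicPattern.M3:
        for v in sorted(g.nodes):
            for a, b, c in combinations(sorted(g.neighbors(v)), 3):
                out.append(Embedding([(a, v), (b, v), (c, v)]))
    elif pid is BasicPattern.M2:
        for u, v in g.sorted_edges():
            for w in sorted(g.neighbors(u) & g.neighbors(v)):
                if w > v:  # sorted triple u < v < w emits each triangle once
                    out.append(Embedding([(u, v), (v, w), (u, w)]))
    elif pid is BasicPattern.M4:
        for u, v in g.sorted_edges():  # (u, v) is the middle edge
            for a in sorted(g.neighbors(u) - {v}):
                for b in sorted(g.neighbors(v) - {u}):
                    if a != b:
                        out.append(Embedding([(a, u), (u, v), (v, b)]))
    else:  # pragma: no cover
        raise ValueError(pid)
    out.sort()
    return out


# ---------------------------------------------------------------------------
# role extraction
# ---------------------------------------------------------------------------

def _m1_roles(emb: Embedding) -> tuple[NodeId, NodeId, NodeId]:
    """(centre, end_a, end_b) of a 2-edge path."""
    (e1, e2) = sorted(emb.edge_set)
    (c,) = set(e1) & set(e2)
    a, b = sorted(emb.node_set - {c})
    return c, a, b


def _m3_roles(emb: Embedding) -> tuple[NodeId, tuple[NodeId, ...]]:
    counts: dict[NodeId, int] = {}
    for u, v in emb.edge_set:
        counts[u] = counts.get(u, 0) + 1
        counts[v] = counts.get(v, 0) + 1
    centre = max(counts, key=counts.get)
    return centre, tuple(sorted(emb.node_set - {centre}))


def _m4_roles(emb: Embedding) -> tuple[NodeId, NodeId, NodeId, NodeId]:
    """Path order (a, u, v, b): edges (a,u), (u,v), (v,b)."""
    counts: dict[NodeId, int] = {}
    adj: dict[NodeId, set[NodeId]] = {}
    for u, v in emb.edge_set:
        counts[u] = counts.get(u, 0) + 1
        counts[v] = counts.get(v, 0) + 1
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    ends = sorted(n for n, k in counts.items() if k == 1)
    a = ends[0]
    (u,) = adj[a]
    (v,) = adj[u] - {a}
    (b,) = adj[v] - {u}
    return a, u, v, b


def _validate(g: NetworkGraph, emb: Embedding, pid: BasicPattern) -> None:
    if not emb.edge_set <= g.edges:
        raise ValueError("embedding has edges outside the host graph")
    counts: dict[NodeId, int] = {}
    for u, v in emb.edge_set:
        counts[u] = counts.get(u, 0) + 1
        counts[v] = counts.get(v, 0) + 1
    if tuple(sorted(counts.values())) != pid.degree_vector:
        raise ValueError(f"embedding is not an instance of {pid.value}")


# ---------------------------------------------------------------------------
# F2 (edge-overlap) closed forms
# ---------------------------------------------------------------------------

def _cn(g: NetworkGraph, u: NodeId, v: NodeId) -> int:
    """|N(u) ∩ N(v)|: common-neighbour (per-edge triangle) count."""
    return len(g.neighbors(u) & g.neighbors(v))


def _a(g: NetworkGraph, u: NodeId, v: NodeId) -> int:
    return 1 if g.has_edge(u, v) else 0


def _f2_m1(g: NetworkGraph, emb: Embedding) -> int:
    c, a, b = _m1_roles(emb)
    return 2 * g.degree(c) + g.degree(a) + g.degree(b) - 6


def _f2_m2(g: NetworkGraph, emb: Embedding) -> int:
    # other triangles sharing an edge: each shared edge contributes its
    # common-neighbour count; the embedding itself is counted once per edge
    u, v, w = sorted(emb.node_set)
    return _cn(g, u, v) + _cn(g, v, w) + _cn(g, u, w) - 3


def _f2_m3(g: NetworkGraph, emb: Embedding) -> int:
    c, leaves = _m3_roles(emb)
    dc = g.degree(c)
    total = 3 * comb(dc - 1, 2) + sum(comb(g.degree(l) - 1, 2) for l in leaves)
    # stars containing two spokes are centred at c: d(c)-2 third-leaf
    # choices per spoke pair; all three spokes -> the embedding itself
    return total - 3 * (dc - 2) + 1 - 1


def _m4_per_edge(g: NetworkGraph, x: NodeId, y: NodeId) -> int:
    """Number of 3-edge paths containing edge (x, y)."""
    mid = (g.degree(x) - 1) * (g.degree(y) - 1) - _cn(g, x, y)
    end = sum(g.degree(w) - 1 - _a(g, w, x) for w in g.neighbors(y) - {x})
    end += sum(g.degree(w) - 1 - _a(g, w, y) for w in g.neighbors(x) - {y})
    return mid + end


def _f2_m4(g: NetworkGraph, emb: Embedding) -> int:
    a, u, v, b = _m4_roles(emb)
    singles = (_m4_per_edge(g, a, u) + _m4_per_edge(g, u, v)
               + _m4_per_edge(g, v, b))
    # paths containing two adjacent edges of the embedding
    pair_au_uv = g.degree(v) + g.degree(a) - 2 - 2 * _a(g, a, v)
    pair_uv_vb = g.degree(u) + g.degree(b) - 2 - 2 * _a(g, u, b)
    # paths containing both end edges: joined by a middle edge between an
    # endpoint of each; (u,v) reproduces the embedding itself
    pair_ends = 1 + _a(g, u, b) + _a(g, a, v) + _a(g, a, b)
    triple = 1
    return singles - (pair_au_uv + pair_uv_vb + pair_ends) + triple - 1


# ---------------------------------------------------------------------------
# F3 (node-overlap): per-node counts + constrained placement counter
# ---------------------------------------------------------------------------

def _n1_m1(g: NetworkGraph, v: NodeId) -> int:
    return comb(g.degree(v), 2) + sum(g.degree(w) - 1 for w in g.neighbors(v))


def _n1_m2(g: NetworkGraph, v: NodeId) -> int:
    return sum(_cn(g, v, w) for w in g.neighbors(v)) // 2


def _n1_m3(g: NetworkGraph, v: NodeId) -> int:
    return comb(g.degree(v), 3) + sum(comb(g.degree(w) - 1, 2) for w in g.neighbors(v))


def _n1_m4(g: NetworkGraph, v: NodeId) -> int:
    end = 0
    for a in g.neighbors(v):
        for b in g.neighbors(a) - {v}:
            end += g.degree(b) - 1 - _a(g, b, v)
    internal = 0
    for a in g.neighbors(v):
        for b in g.neighbors(v) - {a}:
            internal += g.degree(b) - 1 - _a(g, a, b)
    return end + internal


_N1 = {BasicPattern.M1: _n1_m1, BasicPattern.M2: _n1_m2,
       BasicPattern.M3: _n1_m3, BasicPattern.M4: _n1_m4}


def _template_adj(pid: BasicPattern) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {}
    for p, q in pid.template_edges:
        adj.setdefault(p, set()).add(q)
        adj.setdefault(q, set()).add(p)
    return adj


def _complete_placements(g: NetworkGraph, tadj: dict[int, set[int]],
                         assign: dict[int, NodeId]) -> int:
    """Count completions of a partial position->node placement.

    Free positions are anchored through already-placed template neighbours,
    so candidates come from (intersections of) host neighbourhoods only.
    """
    free = [p for p in tadj if p not in assign]
    if not free:
        return 1
    p = max(free, key=lambda q: sum(1 for r in tadj[q] if r in assign))
    anchors = [assign[r] for r in tadj[p] if r in assign]
    cands = set(g.neighbors(anchors[0]))
    for anchor in anchors[1:]:
        cands &= g.neighbors(anchor)
    used = set(assign.values())
    count = 0
    for c in cands:
        if c in used:
            continue
        assign[p] = c
        count += _complete_placements(g, tadj, assign)
        del assign[p]
    return count


def _n_containing_nodes(g: NetworkGraph, pid: BasicPattern,
                        nodes: Sequence[NodeId]) -> int:
    """Number of embeddings of ``pid`` containing every node in ``nodes``.

    Memoised on the graph: embeddings clustered around hubs share most of
    their node subsets, so the inclusion-exclusion terms are heavily reused.
    """
    return g._memo(("n_contain", pid.value, tuple(nodes)),
                   lambda: _n_containing_nodes_uncached(g, pid, nodes))


def _n_containing_nodes_uncached(g: NetworkGraph, pid: BasicPattern,
                                 nodes: Sequence[NodeId]) -> int:
    if len(nodes) == 1:
        return _N1[pid](g, nodes[0])
    tadj = _template_adj(pid)
    positions = sorted(tadj)
    total = 0
    for slots in permutations(positions, len(nodes)):
        assign = dict(zip(slots, nodes))
        ok = True
        for p, q in pid.template_edges:
            if p in assign and q in assign and not g.has_edge(assign[p], assign[q]):
                ok = False
                break
        if ok:
            total += _complete_placements(g, tadj, assign)
    return total // pid.automorphisms


def _f3_overlap(g: NetworkGraph, emb: Embedding, pid: BasicPattern) -> int:
    # inclusion-exclusion over the embedding's node subsets; subtract the
    # embedding itself
    nodes = sorted(emb.node_set)
    total = 0
    for r in range(1, len(nodes) + 1):
        sign = 1 if r % 2 == 1 else -1
        for sub in combinations(nodes, r):
            total += sign * _n_containing_nodes(g, pid, sub)
    return total - 1


_F2 = {BasicPattern.M1: _f2_m1, BasicPattern.M2: _f2_m2,
       BasicPattern.M3: _f2_m3, BasicPattern.M4: _f2_m4}


def algebraic_overlap_count(g: NetworkGraph, emb: Embedding,
                            pid: BasicPattern,
                            measure: Measure = Measure.F2) -> int:
    """Overlap-graph degree of ``emb``: the number of *other* embeddings of
    the same basic pattern sharing >= 1 edge (F2) or >= 1 node (F3).

    Computed from host degrees, common-neighbour counts and local
    neighbour sums — no pairwise embedding comparisons.
    """
    _validate(g, emb, pid)
    if Measure(measure) is Measure.F2:
        return _F2[pid](g, emb)
    return _f3_overlap(g, emb, pid)


# ---------------------------------------------------------------------------
# brute-force fallback (debug switch and test oracle)
# ---------------------------------------------------------------------------

def brute_force_overlap_counts(embeddings: Sequence[Embedding],
                               measure: Measure = Measure.F2) -> list[int]:
    """O(k^2) pairwise overlap degrees, for validation and debugging."""
    measure = Measure(measure)
    counts = [0] * len(embeddings)
    for i, j in combinations(range(len(embeddings)), 2):
        a, b = embeddings[i], embeddings[j]
        if measure is Measure.F2:
            hit = bool(a.edge_set & b.edge_set)
        else:
            hit = bool(a.node_set & b.node_set)
        if hit:
            counts[i] += 1
            counts[j] += 1
    return counts


def enumerate_connected_patterns(n_edges: int) -> list[tuple[tuple[int, int], ...]]:
    """All non-isomorphic connected graphs with exactly ``n_edges`` edges.

    Exhaustive: enumerate edge subsets of the complete graph on 2*n_edges
    labelled vertices, keep connected ones, and bucket by isomorphism.
    Used to verify that M1-M4 are exactly the 2- and 3-edge topologies.
    """
    from .graph_core import connected
    from .isomorphism import Pattern, classify

    n_vertices = 2 * n_edges
    all_edges = list(combinations(range(n_vertices), 2))
    reps: list[Pattern] = []
    for subset in combinations(all_edges, n_edges):
        edges = tuple((str(u), str(v)) for u, v in subset)
        if not connected(edges):
            continue
        pat = Pattern(edges)
        if classify(pat, reps) is None:
            reps.append(pat)
    return [p.anonymized_edges() for p in reps]
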