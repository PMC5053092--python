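"""Canonical-label filters and the exact isomorphism test.

Candidate subgraphs produced by joins must be grouped into equivalence
classes of isomorphic patterns.  Exact isomorphism testing is expensive, so
two isomorphism-invariant node summaries act as a filter cascade:

1. the *degree vector* — the sorted multiset of within-pattern degrees;
2. the *nodes vector* — per-node labels combining shortest-path distances
   and degrees, label(v_i) = sum_j 2^(x - x_ij - d(v_j)) where x is the
   pattern diameter and x_ij the i-j shortest-path length (the j = i self
   term, with x_ii = 0, is included).

Only candidates that survive both filters receive the exact backtracking
bijection test.  Patterns are compared *as bare edge sets* (non-induced
semantics): adjacencies the host graph happens to add are irrelevant.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Optional, Sequence

from .graph_core import EdgeKey, NodeId, edge_key

#: absolute tolerance when comparing nodes-vector labels (dyadic rationals,
#: so this only guards accumulated float error)
LABEL_TOL = 1e-9


def _pattern_adj(edges: Iterable[tuple[NodeId, NodeId]]) -> dict[NodeId, set[NodeId]]:
    adj: dict[NodeId, set[NodeId]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    if not adj:
        raise ValueError("empty edge set")
    return adj


def _check_connected(adj: dict[NodeId, set[NodeId]]) -> None:
    start = next(iter(adj))
    seen = {start}
    queue = deque([start])
    while queue:
        for m in adj[queue.popleft()]:
            if m not in seen:
                seen.add(m)
                queue.append(m)
    if len(seen) != len(adj):
        raise ValueError("edge set spans a disconnected subgraph")


def degree_vector(edges: Iterable[tuple[NodeId, NodeId]]) -> tuple[int, ...]:
    """Sorted multiset of node degrees within the subgraph spanned by edges."""
    adj = _pattern_adj(edges)
    _check_connected(adj)
    return tuple(sorted(len(s) for s in adj.values()))


def _bfs_distances(adj: dict[NodeId, set[NodeId]], source: NodeId) -> dict[NodeId, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        n = queue.popleft()
        for m in adj[n]:
            if m not in dist:
                dist[m] = dist[n] + 1
                queue.append(m)
    return dist


def nodes_vector(edges: Iterable[tuple[NodeId, NodeId]]) -> tuple[float, ...]:
    """Sorted per-node distance/degree labels (the second filter)."""
    adj = _pattern_adj(edges)
    _check_connected(adj)
    nodes = sorted(adj)
    dist = {n: _bfs_distances(adj, n) for n in nodes}
    diameter = max(max(d.values()) for d in dist.values())
    labels = []
    for i in nodes:
        labels.append(sum(2.0 ** (diameter - dist[i][j] - len(adj[j])) for j in nodes))
    return tuple(sorted(labels))


def _vectors_equal(a: Sequence[float], b: Sequence[float], tol: float = LABEL_TOL) -> bool:
    return len(a) == len(b) and all(abs(x - y) <= tol for x, y in zip(a, b))


class Pattern:
    """A motif topology: a representative edge set plus cached invariants."""

    __slots__ = ("edge_set", "degree_vector", "nodes_vector", "n_nodes", "n_edges")

    def __init__(self, edges: Iterable[tuple[NodeId, NodeId]]) -> None:
        keys = {edge_key(u, v) for u, v in edges}
        self.edge_set: tuple[EdgeKey, ...] = tuple(sorted(keys))
        self.degree_vector = degree_vector(keys)
        self.nodes_vector = nodes_vector(keys)
        self.n_nodes = len({n for e in keys for n in e})
        self.n_edges = len(keys)

    def anonymized_edges(self) -> tuple[tuple[int, int], ...]:
        """Representative edge set over integer labels 0..k-1.

        Nodes are numbered in BFS order from a deterministically chosen
        root (highest degree, lexicographic tie-break).  This is a stable
        representative for reporting, not a canonical form across
        isomorphic relabelings.
        """
        adj = _pattern_adj(self.edge_set)
        root = min(adj, key=lambda n: (-len(adj[n]), n))
        order: dict[NodeId, int] = {root: 0}
        queue = deque([root])
        while queue:
            n = queue.popleft()
            for m in sorted(adj[n], key=lambda x: (-len(adj[x]), x)):
                if m not in order:
                    order[m] = len(order)
                    queue.append(m)
        return tuple(sorted(tuple(sorted((order[u], order[v]))) for u, v in self.edge_set))

    def __repr__(self) -> str:
        return f"Pattern(nodes={self.n_nodes}, edges={self.n_edges})"


def _backtrack_isomorphism(adj1: dict[NodeId, set[NodeId]],
                           adj2: dict[NodeId, set[NodeId]]) -> bool:
    """Backtracking bijection search, descending-degree order with
    degree-compatibility and adjacency-consistency pruning."""
    nodes1 = sorted(adj1, key=lambda n: (-len(adj1[n]), n))
    # prefer nodes adjacent to already-mapped ones for early pruning
    ordered: list[NodeId] = []
    placed: set[NodeId] = set()
    remaining = list(nodes1)
    while remaining:
        pick = None
        for n in remaining:
            if any(m in placed for m in adj1[n]):
                pick = n
                break
        if pick is None:
            pick = remaining[0]
        ordered.append(pick)
        placed.add(pick)
        remaining.remove(pick)

    by_degree2: dict[int, list[NodeId]] = {}
    for n in adj2:
        by_degree2.setdefault(len(adj2[n]), []).append(n)

    mapping: dict[NodeId, NodeId] = {}
    used: set[NodeId] = set()

    def extend(i: int) -> bool:
        if i == len(ordered):
            return True
        u = ordered[i]
        for v in by_degree2.get(len(adj1[u]), ()):
            if v in used:
                continue
            ok = True
            for w in adj1[u]:
                if w in mapping and mapping[w] not in adj2[v]:
                    ok = False
                    break
            if ok:
                # consistency both ways: mapped neighbors of v must be
                # exactly the images of u's mapped neighbors
                for w, img in mapping.items():
                    if (w in adj1[u]) != (img in adj2[v]):
                        ok = False
                        break
            if ok:
                mapping[u] = v
                used.add(v)
                if extend(i + 1):
                    return True
                del mapping[u]
                used.remove(v)
        return False

    return extend(0)


def are_isomorphic(e1: Iterable[tuple[NodeId, NodeId]],
                   e2: Iterable[tuple[NodeId, NodeId]]) -> bool:
    """Exact test: does an edge-preserving node bijection exist?"""
    adj1 = _pattern_adj(e1)
    adj2 = _pattern_adj(e2)
    if len(adj1) != len(adj2):
        return False
    n1 = sum(len(s) for s in adj1.values())
    n2 = sum(len(s) for s in adj2.values())
    if n1 != n2:
        return False
    if sorted(len(s) for s in adj1.values()) != sorted(len(s) for s in adj2.values()):
        return False
    return _backtrack_isomorphism(adj1, adj2)


def classify(candidate: Pattern | Iterable[tuple[NodeId, NodeId]],
             patterns: Sequence[Pattern]) -> Optional[int]:
    """Index of the pattern isomorphic to ``candidate``, or None if new.

    Cascade: degree-vector equality, then nodes-vector equality (within
    tolerance), then the exact test.  Raises if two patterns both claim the
    candidate (the class list must be pairwise non-isomorphic).
    """
    cand = candidate if isinstance(candidate, Pattern) else Pattern(candidate)
    match: Optional[int] = None
    for i, p in enumerate(patterns):
        if p.degree_vector != cand.degree_vector:
            continue
        if not _vectors_equal(p.nodes_vector, cand.nodes_vector):
            continue
        if are_isomorphic(p.edge_set, cand.edge_set):
            if match is not None:
                raise RuntimeError(
                    "equivalence classes are not pairwise non-isomorphic")
            match = i
    return match
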