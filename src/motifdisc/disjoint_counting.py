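"""Disjoint-embedding extraction: the F2/F3 frequency of a pattern.

The disjoint frequency of a pattern is the size of a maximum independent
set (MIS) in its *overlap graph* — the graph whose vertices are the
pattern's embeddings, adjacent when two embeddings share an edge (F2) or a
node (F3).  Exact MIS is NP-hard, so a greedy minimum-degree heuristic is
used: repeatedly accept the embedding overlapping the fewest others, then
remove it and its neighbours, until the overlap graph is empty.

Two implementations exist:

* ``greedy_mis`` materialises the overlap graph (pairwise tests); used for
  derived patterns, whose embedding lists are short.
* ``greedy_mis_algebraic`` is reserved for the four basic building
  patterns: overlap degrees come from the algebraic closed forms, the
  embeddings are processed in ascending overlap-count order, and a running
  used-edge/used-node set replaces explicit neighbour deletion.  Overlap
  adjacency is never materialised.

Both produce maximal independent sets and are deterministic (ties broken
by the canonical embedding key).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

from .basic_patterns import BasicPattern, Measure, algebraic_overlap_count
from .graph_core import Embedding, NetworkGraph
from .isomorphism import Pattern


@dataclass
class OverlapGraph:
    """Explicit overlap graph over embedding indices."""

    embeddings: list[Embedding]
    adjacency: dict[int, set[int]]

    def degree(self, i: int) -> int:
        return len(self.adjacency[i])


@dataclass
class EquivalenceClass:
    """A pattern together with its embeddings and frequency counts.

    ``f1`` is the plain embedding count; ``f_disjoint`` the disjoint (F2 or
    F3) count.  ``basic_id`` is set for the four basic building patterns,
    which are entitled to the algebraic MIS path.
    """

    pattern: Pattern
    all_embeddings: list[Embedding] = field(default_factory=list)
    disjoint_embeddings: list[Embedding] = field(default_factory=list)
    basic_id: Optional[BasicPattern] = None

    @property
    def f1(self) -> int:
        return len(self.all_embeddings)

    @property
    def f_disjoint(self) -> int:
        return len(self.disjoint_embeddings)


def _overlaps(a: Embedding, b: Embedding, measure: Measure) -> bool:
    if measure is Measure.F2:
        return bool(a.edge_set & b.edge_set)
    return bool(a.node_set & b.node_set)


def build_overlap_graph(embeddings: Sequence[Embedding],
                        measure: Measure = Measure.F2) -> OverlapGraph:
    """Pairwise overlap tests; symmetric adjacency, no self-adjacency."""
    measure = Measure(measure)
    if len(set(embeddings)) != len(embeddings):
        raise ValueError("embeddings must be pairwise distinct")
    adj: dict[int, set[int]] = {i: set() for i in range(len(embeddings))}
    for i, j in combinations(range(len(embeddings)), 2):
        if _overlaps(embeddings[i], embeddings[j], measure):
            adj[i].add(j)
            adj[j].add(i)
    return OverlapGraph(list(embeddings), adj)


def greedy_mis(og: OverlapGraph) -> set[int]:
    """Iterated minimum-degree selection with degree updates.

    Ties are broken by the canonical key of the candidate's embedding, so
    the result is reproducible.
    """
    alive: dict[int, set[int]] = {i: set(s) for i, s in og.adjacency.items()}
    chosen: set[int] = set()
    while alive:
        pick = min(alive, key=lambda i: (len(alive[i]), og.embeddings[i].key))
        chosen.add(pick)
        dead = {pick} | alive[pick]
        for d in dead:
            for nbr in alive[d]:
                if nbr not in dead:
                    alive[nbr].discard(d)
            del alive[d]
    return chosen


def greedy_mis_algebraic(g: NetworkGraph, embeddings: Sequence[Embedding],
                         pid: BasicPattern,
                         measure: Measure = Measure.F2,
                         brute_force: bool = False) -> set[int]:
    """Greedy MIS for a basic pattern without materialising adjacency.

    Overlap counts come from :func:`algebraic_overlap_count` (or the O(k^2)
    brute force when ``brute_force`` is set, a correctness-debugging
    switch).  Embeddings are scanned in ascending overlap-count order and
    accepted whenever they touch no edge (F2) / node (F3) already used by
    an accepted embedding.
    """
    measure = Measure(measure)
    if brute_force:
        from .basic_patterns import brute_force_overlap_counts
        counts = brute_force_overlap_counts(embeddings, measure)
    else:
        counts = [algebraic_overlap_count(g, e, pid, measure) for e in embeddings]
    order = sorted(range(len(embeddings)),
                   key=lambda i: (counts[i], embeddings[i].key))
    chosen: set[int] = set()
    used: set = set()
    for i in order:
        emb = embeddings[i]
        items = emb.edge_set if measure is Measure.F2 else emb.node_set
        if used.isdisjoint(items):
            chosen.add(i)
            used |= items
    return chosen


def _check_independent_maximal(embeddings: Sequence[Embedding],
                               chosen: set[int], measure: Measure) -> None:
    """Cheap certificate that a greedy output is an independent set and
    maximal; violated only by an implementation bug."""
    used_edges: set = set()
    used_nodes: set = set()
    for i in chosen:
        e = embeddings[i]
        if measure is Measure.F2:
            if used_edges & e.edge_set:
                raise AssertionError("selected embeddings are not edge-disjoint")
            used_edges |= e.edge_set
        else:
            if used_nodes & e.node_set:
                raise AssertionError("selected embeddings are not node-disjoint")
            used_nodes |= e.node_set
    for i, e in enumerate(embeddings):
        if i in chosen:
            continue
        items = e.edge_set if measure is Measure.F2 else e.node_set
        free = used_edges if measure is Measure.F2 else used_nodes
        if free.isdisjoint(items):
            raise AssertionError("independent set is not maximal")


def count_frequency(g: NetworkGraph, ec: EquivalenceClass,
                    measure: Measure = Measure.F2,
                    verify: bool = True) -> int:
    """Fill ``ec.disjoint_embeddings`` and return the disjoint frequency.

    Basic patterns take the algebraic path; derived patterns the explicit
    overlap graph.
    """
    measure = Measure(measure)
    if ec.basic_id is not None:
        chosen = greedy_mis_algebraic(g, ec.all_embeddings, ec.basic_id, measure)
    else:
        chosen = greedy_mis(build_overlap_graph(ec.all_embeddings, measure))
    if verify:
        _check_independent_maximal(ec.all_embeddings, chosen, measure)
    ec.disjoint_embeddings = [ec.all_embeddings[i] for i in sorted(chosen)]
    ec.disjoint_embeddings.sort()
    return ec.f_disjoint
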