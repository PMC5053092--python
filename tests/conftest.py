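"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random
from itertools import combinations, permutations

import networkx as nx
import pytest

from motifdisc import Embedding, NetworkGraph, build_overlap_graph, fig1_graph
from motifdisc.basic_patterns import Measure

# the three embeddings of the triangle-with-pendant pattern in the
# worked-example graph (S1, S2, S3)
S1_EDGES = (("a", "b"), ("a", "c"), ("b", "c"), ("b", "e"))
S2_EDGES = (("e", "f"), ("f", "g"), ("e", "g"), ("e", "d"))
S3_EDGES = (("e", "f"), ("f", "g"), ("e", "g"), ("b", "e"))
S4_EDGES = (("b", "e"), ("d", "e"), ("e", "f"), ("e", "g"))


@pytest.fixture
def fig1():
    return fig1_graph()


@pytest.fixture
def fig1c_embeddings():
    return [Embedding(S1_EDGES), Embedding(S2_EDGES), Embedding(S3_EDGES)]


# ---------------------------------------------------------------------------
# oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------

def brute_force_isomorphic(e1, e2) -> bool:
    """Try every node bijection (patterns <= 8 nodes)."""
    adj1: dict = {}
    adj2: dict = {}
    for adj, edges in ((adj1, e1), (adj2, e2)):
        for u, v in edges:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
    n1, n2 = sorted(adj1), sorted(adj2)
    if len(n1) != len(n2):
        return False
    eset2 = {frozenset(e) for e in e2}
    for perm in permutations(n2):
        mapping = dict(zip(n1, perm))
        if {frozenset((mapping[u], mapping[v])) for u, v in e1} == eset2:
            return True
    return False


def exact_mis_size(embeddings, measure) -> int:
    """Exact maximum independent set of the overlap graph, via the
    complement's maximum clique (exponential; tiny instances only)."""
    og = build_overlap_graph(embeddings, Measure(measure))
    h = nx.Graph()
    h.add_nodes_from(og.adjacency)
    h.add_edges_from((i, j) for i, nbrs in og.adjacency.items() for j in nbrs if i < j)
    clique, _ = nx.max_weight_clique(nx.complement(h), weight=None)
    return len(clique)


def all_embeddings_of(g: NetworkGraph, pattern_edges) -> list[Embedding]:
    """Exhaustive embedding list (F1 support) by VF2 monomorphism search."""
    host = g.to_networkx()
    template = nx.Graph()
    template.add_edges_from(pattern_edges)
    matcher = nx.algorithms.isomorphism.GraphMatcher(host, template)
    seen = {}
    for mapping in matcher.subgraph_monomorphisms_iter():
        inv = {v: k for k, v in mapping.items()}
        emb = Embedding([(inv[u], inv[v]) for u, v in template.edges])
        seen[emb.key] = emb
    return sorted(seen.values())


def random_connected_pattern(rng: random.Random, max_edges: int = 12):
    """A random connected edge set (grown edge by edge)."""
    n_edges = rng.randint(2, max_edges)
    nodes = ["v0", "v1"]
    edges = {("v0", "v1")}
    while len(edges) < n_edges:
        u = rng.choice(nodes)
        if rng.random() < 0.4 and len(nodes) > 2:
            v = rng.choice(nodes)
            if u == v:
                continue
            e = tuple(sorted((u, v)))
            if e in edges:
                continue
        else:
            v = f"v{len(nodes)}"
            nodes.append(v)
            e = tuple(sorted((u, v)))
        edges.add(e)
    return sorted(edges)


def relabelled(edges, rng: random.Random):
    """The same pattern under a random node relabelling."""
    nodes = sorted({n for e in edges for n in e})
    new = [f"w{i}" for i in range(len(nodes))]
    rng.shuffle(new)
    mapping = dict(zip(nodes, new))
    return [(mapping[u], mapping[v]) for u, v in edges]
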