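"""Synthetic networks and fixtures.

Protein-protein interaction networks are scale-free-like, so the synthetic
benchmark graphs are Barabási-Albert preferential-attachment graphs with a
density (edges added per arriving node) of 1-4, covering the 1-4
edges-per-node range typical of PPI data; density 2 (mean degree about 4)
is the default study condition.  The module also provides the seven-node
worked-example graph used throughout the documentation and generators of
non-isomorphic same-size graph pairs for measuring the degree-vector
filter's rejection rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_core import NetworkGraph

#: Worked-example graph: seven nodes a-g, eight edges, two triangles
#: bridged by the hub e.
FIG1_EDGES = (("a", "b"), ("a", "c"), ("b", "c"), ("b", "e"),
              ("e", "d"), ("e", "f"), ("f", "g"), ("e", "g"))


def fig1_graph() -> NetworkGraph:
    """The 7-node / 8-edge worked-example graph."""
    return NetworkGraph(FIG1_EDGES)


@dataclass
class BAConfig:
    """Barabási-Albert generator settings.

    density is the number of edges each arriving node attaches; the graph
    starts from a seed clique of density + 1 nodes, so |E| =
    C(density+1, 2) + (n_nodes - density - 1) * density.
    """

    n_nodes: int
    density: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.density < self.n_nodes):
            raise ValueError("need n_nodes > density >= 1")


def barabasi_albert(cfg: BAConfig) -> NetworkGraph:
    """Preferential-attachment graph per ``cfg`` (node ids 'n0', 'n1', ...)."""
    initial = nx.complete_graph(cfg.density + 1)
    g = nx.barabasi_albert_graph(cfg.n_nodes, cfg.density,
                                 seed=cfg.seed, initial_graph=initial)
    g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
    return NetworkGraph.from_networkx(g)


def _degseq(g: NetworkGraph) -> list[int]:
    return g.degree_sequence()


def nonisomorphic_pairs(n_pairs: int, size_range: tuple[int, int] = (20, 60),
                        density: int = 2, seed: int = 0
                        ) -> list[tuple[NetworkGraph, NetworkGraph]]:
    """Pairs of independent BA graphs with identical node and edge counts,
    regenerated whenever a pair happens to be isomorphic.

    Matched parameters make |V| and |E| equal by construction.  The
    isomorphism rejection first compares degree sequences (different
    sequences prove non-isomorphism) and only then runs VF2.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[NetworkGraph, NetworkGraph]] = []
    while len(pairs) < n_pairs:
        n = int(rng.integers(size_range[0], size_range[1] + 1))
        s1, s2 = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
        g1 = barabasi_albert(BAConfig(n_nodes=n, density=density, seed=s1))
        g2 = barabasi_albert(BAConfig(n_nodes=n, density=density, seed=s2))
        if _degseq(g1) == _degseq(g2):
            if nx.is_isomorphic(g1.to_networkx(), g2.to_networkx()):
                continue
        pairs.append((g1, g2))
    return pairs


def degree_vector_filter_rate(pairs) -> float:
    """Fraction of pairs whose sorted degree sequences already differ."""
    if not pairs:
        raise ValueError("no pairs")
    hits = sum(1 for g1, g2 in pairs if _degseq(g1) != _degseq(g2))
    return hits / len(pairs)
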