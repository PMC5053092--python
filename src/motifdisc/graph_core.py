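"""Graph data model, file I/O, and preprocessing.

The target network is an undirected simple graph over opaque string node
identifiers (protein IDs in practice).  A subgraph occurrence (*embedding*)
is identified purely by its edge set: because every embedding considered by
the discovery algorithm is connected, the edge set determines the node set.
"""

from __future__ import annotations

import logging
from collections import deque
from typing import Iterable, Iterator

import networkx as nx

log = logging.getLogger(__name__)

NodeId = str
EdgeKey = tuple[str, str]


def edge_key(u: NodeId, v: NodeId) -> EdgeKey:
    """Canonical unordered-pair key: endpoints sorted lexicographically."""
    return (u, v) if u <= v else (v, u)


class GraphParseError(ValueError):
    """Raised for malformed edge-list input."""


class NetworkGraph:
    """Simple undirected graph with adjacency and degree access.

    Invariants: no self-loops, no parallel edges, symmetric adjacency.
    """

    __slots__ = ("_adj", "_scratch")

    def __init__(self, edges: Iterable[tuple[NodeId, NodeId]] = (),
                 nodes: Iterable[NodeId] = ()) -> None:
        self._adj: dict[NodeId, set[NodeId]] = {}
        self._scratch: dict = {}
        for n in nodes:
            self.add_node(n)
        for u, v in edges:
            self.add_edge(u, v)

    def add_node(self, n: NodeId) -> None:
        self._adj.setdefault(str(n), set())
        if self._scratch:
            self._scratch.clear()

    def add_edge(self, u: NodeId, v: NodeId) -> None:
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"self-loop on node {u!r} not allowed")
        self._adj.setdefault(u, set()).add(v)
        self._adj.setdefault(v, set()).add(u)
        if self._scratch:
            self._scratch.clear()

    def _memo(self, key, fn):
        """Per-graph memo for derived quantities; cleared on mutation."""
        try:
            return self._scratch[key]
        except KeyError:
            val = fn()
            self._scratch[key] = val
            return val

    # -- accessors ---------------------------------------------------------
    @property
    def nodes(self) -> set[NodeId]:
        return set(self._adj)

    @property
    def edges(self) -> set[EdgeKey]:
        return {edge_key(u, v) for u, nbrs in self._adj.items() for v in nbrs if u <= v}

    def sorted_edges(self) -> list[EdgeKey]:
        return sorted(self.edges)

    def neighbors(self, n: NodeId) -> set[NodeId]:
        return self._adj[n]

    def degree(self, n: NodeId) -> int:
        return len(self._adj[n])

    def has_edge(self, u: NodeId, v: NodeId) -> bool:
        return v in self._adj.get(u, ())

    def has_node(self, n: NodeId) -> bool:
        return n in self._adj

    def number_of_nodes(self) -> int:
        return len(self._adj)

    def number_of_edges(self) -> int:
        return sum(len(s) for s in self._adj.values()) // 2

    def degree_sequence(self) -> list[int]:
        """Sorted (ascending) multiset of node degrees."""
        return sorted(len(s) for s in self._adj.values())

    def __contains__(self, n: NodeId) -> bool:
        return n in self._adj

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkGraph):
            return NotImplemented
        return self._adj == other._adj

    def __repr__(self) -> str:
        return (f"NetworkGraph(|V|={self.number_of_nodes()}, "
                f"|E|={self.number_of_edges()})")

    def copy(self) -> "NetworkGraph":
        g = NetworkGraph()
        g._adj = {n: set(s) for n, s in self._adj.items()}
        g._scratch = {}
        return g

    # -- interop -----------------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._adj)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "NetworkGraph":
        out = cls(nodes=(str(n) for n in g.nodes))
        for u, v in g.edges:
            if u != v:
                out.add_edge(str(u), str(v))
        return out


class Embedding:
    """A concrete connected subgraph instance, identified by its edge set.

    The key (edges canonically ordered within each pair and sorted across
    pairs) makes duplicate detection and tie-breaking exact and stable.
    """

    __slots__ = ("key", "edge_set", "node_set")

    def __init__(self, edges: Iterable[tuple[NodeId, NodeId]]) -> None:
        keys = {edge_key(u, v) for u, v in edges}
        if not keys:
            raise ValueError("an embedding needs at least one edge")
        self.key: tuple[EdgeKey, ...] = tuple(sorted(keys))
        self.edge_set: frozenset[EdgeKey] = frozenset(keys)
        self.node_set: frozenset[NodeId] = frozenset(n for e in keys for n in e)

    def n_edges(self) -> int:
        return len(self.edge_set)

    def n_nodes(self) -> int:
        return len(self.node_set)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Embedding):
            return NotImplemented
        return self.key == other.key

    def __lt__(self, other: "Embedding") -> bool:
        return self.key < other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __repr__(self) -> str:
        return f"Embedding({list(self.key)})"


def connected(edges: Iterable[tuple[NodeId, NodeId]]) -> bool:
    """True iff the subgraph spanned by ``edges`` is connected.

    Raises ValueError on an empty edge set.
    """
    adj: dict[NodeId, set[NodeId]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    if not adj:
        raise ValueError("connected() is undefined for an empty edge set")
    start = next(iter(adj))
    seen = {start}
    queue = deque([start])
    while queue:
        n = queue.popleft()
        for m in adj[n]:
            if m not in seen:
                seen.add(m)
                queue.append(m)
    return len(seen) == len(adj)


def read_edge_list(path) -> NetworkGraph:
    """Read a whitespace-delimited edge list ('#' starts a comment line).

    Duplicate and reversed-duplicate lines collapse to one edge; self-loops
    are dropped with a warning (the node is kept).  Raises GraphParseError
    on malformed lines and on an empty graph.
    """
    g = NetworkGraph()
    n_loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise GraphParseError(
                    f"{path}:{lineno}: expected two node identifiers, got {line!r}")
            u, v = tokens[0], tokens[1]
            if u == v:
                n_loops += 1
                g.add_node(u)
                continue
            g.add_edge(u, v)
    if n_loops:
        log.warning("%s: dropped %d self-loop(s)", path, n_loops)
    if g.number_of_nodes() == 0:
        raise GraphParseError(f"{path}: empty graph")
    return g


def write_edge_list(g: NetworkGraph, path) -> None:
    """Write the graph as a sorted edge list; isolated nodes as '# node: x'."""
    with open(path, "w") as fh:
        isolated = sorted(n for n in g.nodes if g.degree(n) == 0)
        for n in isolated:
            fh.write(f"# node: {n}\n")
        for u, v in g.sorted_edges():
            fh.write(f"{u} {v}\n")


def read_graphml(path) -> NetworkGraph:
    return NetworkGraph.from_networkx(nx.read_graphml(path))


def write_graphml(g: NetworkGraph, path) -> None:
    nx.write_graphml(g.to_networkx(), path)


def connected_components(g: NetworkGraph) -> Iterator[set[NodeId]]:
    yield from nx.connected_components(g.to_networkx())


def prune_small_components(g: NetworkGraph, mu: int) -> NetworkGraph:
    """Drop connected components with fewer than ``mu`` nodes.

    Components too small to host a motif of mu nodes cannot contribute
    embeddings, so removing them is lossless preprocessing.
    """
    if mu < 1:
        raise ValueError("mu must be >= 1")
    keep: set[NodeId] = set()
    for comp in connected_components(g):
        if len(comp) >= mu:
            keep |= comp
    out = NetworkGraph(nodes=keep)
    for u, v in g.edges:
        if u in keep and v in keep:
            out.add_edge(u, v)
    return out
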