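"""Join-based motif discovery.

Motifs are grown iteratively: every disjoint instance of every current
pattern is joined with instances of the four basic building patterns, two
instances joining when they share at least one edge (their union, which is
connected by construction, is the candidate).  Candidates are classified
into equivalence classes through the degree-vector / nodes-vector filter
cascade and the exact isomorphism test, deduplicated by canonical edge-set
key, counted with the greedy MIS, and pruned against the frequency
threshold alpha.  Because the disjoint measures F2/F3 are downward closed,
a pattern pruned once can never become frequent again, so pruning is safe.

The search is a heuristic: it finds every frequent topology reachable by
joins, but makes no completeness guarantee on the instance lists.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from math import comb, isqrt
from typing import Optional, Sequence

import networkx as nx

from .basic_patterns import BasicPattern, Measure, enumerate_basic
from .disjoint_counting import EquivalenceClass, count_frequency
from .graph_core import Embedding, NetworkGraph, connected, prune_small_components
from .isomorphism import Pattern, classify

log = logging.getLogger(__name__)


class SizeMode(str, enum.Enum):
    NODES = "nodes"
    EDGES = "edges"


class JoinSource(str, enum.Enum):
    DISJOINT = "disjoint"  # the basic patterns' disjoint instance sets S_i'
    ALL = "all"            # full instance sets S_i (higher recall, slower)


@dataclass
class DiscoveryConfig:
    """Parameters of a discovery run.

    mu is the target motif size, counted in nodes by default (the problem
    definition) or edges (the reporting convention of some tools); alpha
    the minimum disjoint frequency; measure selects edge- (F2) or
    node-disjoint (F3) counting.
    """

    mu: int
    alpha: int = 1
    size_mode: SizeMode = SizeMode.NODES
    measure: Measure = Measure.F2
    join_source: JoinSource = JoinSource.DISJOINT
    seed: int = 0

    def __post_init__(self) -> None:
        self.size_mode = SizeMode(self.size_mode)
        self.measure = Measure(self.measure)
        self.join_source = JoinSource(self.join_source)
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        min_mu = 3 if self.size_mode is SizeMode.NODES else 2
        if self.mu < min_mu:
            raise ValueError(
                f"mu must be >= {min_mu} in {self.size_mode.value} mode "
                "(no pattern is smaller than the basic building patterns)")


@dataclass
class MotifRecord:
    pattern_edges: tuple[tuple[int, int], ...]  # anonymized representative
    n_nodes: int
    n_edges: int
    frequency: int
    embeddings: list[list[tuple[str, str]]]

    def to_dict(self) -> dict:
        return {
            "pattern_edges": [list(e) for e in self.pattern_edges],
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "frequency": self.frequency,
            "embeddings": [[list(e) for e in emb] for emb in self.embeddings],
        }


@dataclass
class MotifReport:
    config: DiscoveryConfig
    records: list[MotifRecord] = field(default_factory=list)

    def frequencies(self) -> list[int]:
        return [r.frequency for r in self.records]

    def to_json(self) -> str:
        return json.dumps({
            "config": {
                "mu": self.config.mu, "alpha": self.config.alpha,
                "size_mode": self.config.size_mode.value,
                "measure": self.config.measure.value,
                "join_source": self.config.join_source.value,
                "seed": self.config.seed,
            },
            "motifs": [r.to_dict() for r in self.records],
        }, indent=2)

    def to_tsv(self) -> str:
        lines = ["pattern_id\tn_nodes\tn_edges\tfrequency\tpattern_edges"]
        for i, r in enumerate(self.records):
            edges = ";".join(f"{u}-{v}" for u, v in r.pattern_edges)
            lines.append(f"P{i}\t{r.n_nodes}\t{r.n_edges}\t{r.frequency}\t{edges}")
        return "\n".join(lines) + "\n"


def join_pair(m: Embedding, b: Embedding) -> Optional[Embedding]:
    """Union of two instances if they share an edge and the union grows m.

    Returns None ("no-join") for disjoint instances and for b ⊆ m.
    """
    if not (m.edge_set & b.edge_set):
        return None
    union = m.edge_set | b.edge_set
    if len(union) == len(m.edge_set):
        return None
    return Embedding(union)


def _size_of(pattern: Pattern, mode: SizeMode) -> int:
    return pattern.n_nodes if mode is SizeMode.NODES else pattern.n_edges


def _emb_oversize(emb: Embedding, cfg: DiscoveryConfig) -> bool:
    if cfg.size_mode is SizeMode.NODES:
        return emb.n_nodes() > cfg.mu
    return emb.n_edges() > cfg.mu


def _max_edges(cfg: DiscoveryConfig) -> int:
    if cfg.size_mode is SizeMode.NODES:
        return comb(cfg.mu, 2)
    return cfg.mu


def seed_basic_classes(g: NetworkGraph, cfg: DiscoveryConfig) -> list[EquivalenceClass]:
    """Enumerate and disjoint-count the four basic classes; alpha-prune."""
    classes: list[EquivalenceClass] = []
    for pid in BasicPattern:
        embs = enumerate_basic(g, pid)
        if not embs:
            continue
        ec = EquivalenceClass(
            pattern=Pattern(tuple((str(u), str(v)) for u, v in pid.template_edges)),
            all_embeddings=embs, basic_id=pid)
        count_frequency(g, ec, cfg.measure)
        if ec.f_disjoint >= cfg.alpha:
            classes.append(ec)
    return classes


def run_iteration(g: NetworkGraph, current: Sequence[EquivalenceClass],
                  basics: Sequence[EquivalenceClass], cfg: DiscoveryConfig,
                  registry: Optional[list[EquivalenceClass]] = None,
                  dead: Optional[set[int]] = None) -> list[EquivalenceClass]:
    """One growth step: join, classify, dedup, count, prune.

    ``registry`` accumulates every class seen so far (so a product
    isomorphic to an earlier pattern merges into that class rather than
    spawning a duplicate); it defaults to a copy of ``current``.  ``dead``
    collects registry indices pruned below alpha — downward closure
    guarantees they can be discarded for good.  Returns the classes that
    gained instances (or are new) and survived pruning.
    """
    if registry is None:
        registry = list(current)
    if dead is None:
        dead = set()
    key_sets: dict[int, set] = {}
    touched: set[int] = set()

    basic_instances: list[Embedding] = []
    for bc in basics:
        pool = (bc.disjoint_embeddings if cfg.join_source is JoinSource.DISJOINT
                else bc.all_embeddings)
        basic_instances.extend(pool)

    for ec in current:
        for m in ec.disjoint_embeddings:
            for b in basic_instances:
                product = join_pair(m, b)
                if product is None or _emb_oversize(product, cfg):
                    continue
                idx = classify(Pattern(product.edge_set), [r.pattern for r in registry])
                if idx is None:
                    new_ec = EquivalenceClass(pattern=Pattern(product.edge_set),
                                              all_embeddings=[product])
                    registry.append(new_ec)
                    idx = len(registry) - 1
                    key_sets[idx] = {product.key}
                    touched.add(idx)
                elif idx not in dead:
                    if idx not in key_sets:
                        key_sets[idx] = {e.key for e in registry[idx].all_embeddings}
                    if product.key not in key_sets[idx]:
                        registry[idx].all_embeddings.append(product)
                        key_sets[idx].add(product.key)
                        touched.add(idx)

    survivors: list[EquivalenceClass] = []
    for idx in sorted(touched):
        ec = registry[idx]
        ec.all_embeddings.sort()
        count_frequency(g, ec, cfg.measure)
        if ec.f_disjoint < cfg.alpha:
            dead.add(idx)
        else:
            survivors.append(ec)
    log.info("iteration: %d candidate classes touched, %d survive alpha=%d",
             len(touched), len(survivors), cfg.alpha)
    return survivors


def _verify_report(g: NetworkGraph, report: MotifReport) -> None:
    """Soundness certificate for every reported motif."""
    host_edges = g.edges
    from .isomorphism import are_isomorphic
    for rec in report.records:
        pat_edges = tuple((str(u), str(v)) for u, v in rec.pattern_edges)
        used_edges: set = set()
        used_nodes: set = set()
        for emb_edges in rec.embeddings:
            eset = {tuple(sorted(e)) for e in emb_edges}
            assert eset <= host_edges, "embedding leaves the host graph"
            assert connected(eset), "embedding is disconnected"
            assert are_isomorphic(eset, pat_edges), \
                "embedding does not match its reported pattern"
            nodes = {n for e in eset for n in e}
            if report.config.measure is Measure.F2:
                assert not (used_edges & eset), "reported embeddings share an edge"
            else:
                assert not (used_nodes & nodes), "reported embeddings share a node"
            used_edges |= eset
            used_nodes |= nodes
        if report.config.measure is Measure.F2:
            assert rec.frequency * rec.n_edges <= g.number_of_edges(), \
                "frequency inflates beyond the host edge budget"
        else:
            assert rec.frequency * rec.n_nodes <= g.number_of_nodes(), \
                "frequency inflates beyond the host node budget"


def _min_component_nodes(cfg: DiscoveryConfig) -> int:
    if cfg.size_mode is SizeMode.NODES:
        return cfg.mu
    # fewest nodes a connected graph with mu edges can have: smallest k
    # with C(k, 2) >= mu
    k = max(2, isqrt(2 * cfg.mu))
    while comb(k, 2) < cfg.mu:
        k += 1
    return k


def find_motifs(g: NetworkGraph, cfg: DiscoveryConfig) -> MotifReport:
    """Full discovery run: seed, iterate joins, harvest, verify, report."""
    g = prune_small_components(g, _min_component_nodes(cfg))
    report = MotifReport(config=cfg)
    if g.number_of_nodes() == 0:
        return report

    basics = seed_basic_classes(g, cfg)
    registry: list[EquivalenceClass] = list(basics)
    dead: set[int] = set()
    harvested: dict[int, EquivalenceClass] = {}

    def consider_harvest(ec: EquivalenceClass) -> None:
        if _size_of(ec.pattern, cfg.size_mode) == cfg.mu and ec.f_disjoint >= cfg.alpha:
            harvested[id(ec)] = ec

    max_edge_budget = _max_edges(cfg)

    def growable(ec: EquivalenceClass) -> bool:
        size = _size_of(ec.pattern, cfg.size_mode)
        if size > cfg.mu:
            return False
        if size < cfg.mu:
            return True
        # at target: in node mode the pattern can still gain edges
        return (cfg.size_mode is SizeMode.NODES
                and ec.pattern.n_edges < max_edge_budget)

    for ec in basics:
        consider_harvest(ec)
    working = [ec for ec in basics if growable(ec)]

    max_iterations = max_edge_budget + 2  # safety bound; joins add >= 1 edge
    iteration = 0
    while working and iteration < max_iterations:
        iteration += 1
        survivors = run_iteration(g, working, basics, cfg, registry, dead)
        for ec in survivors:
            consider_harvest(ec)
        working = [ec for ec in survivors if growable(ec)]

    records = []
    for ec in harvested.values():
        if ec.f_disjoint < cfg.alpha:
            continue
        records.append(MotifRecord(
            pattern_edges=ec.pattern.anonymized_edges(),
            n_nodes=ec.pattern.n_nodes,
            n_edges=ec.pattern.n_edges,
            frequency=ec.f_disjoint,
            embeddings=[[e for e in emb.key] for emb in ec.disjoint_embeddings],
        ))
    records.sort(key=lambda r: (-r.frequency, r.pattern_edges))
    report.records = records
    _verify_report(g, report)
    return report


def count_pattern(g: NetworkGraph, pattern_edges) -> dict[str, int]:
    """F1/F2/F3 of a user-supplied pattern in ``g``.

    Embeddings are enumerated exhaustively by subgraph monomorphism (VF2),
    then disjoint-counted with the greedy MIS — this is the exact-counting
    utility, independent of the join heuristic.
    """
    pat = Pattern(pattern_edges)
    host = g.to_networkx()
    template = nx.Graph()
    template.add_edges_from(pat.edge_set)
    matcher = nx.algorithms.isomorphism.GraphMatcher(host, template)
    seen: dict = {}
    for mapping in matcher.subgraph_monomorphisms_iter():
        inv = {v: k for k, v in mapping.items()}
        emb = Embedding([(inv[u], inv[v]) for u, v in pat.edge_set])
        seen[emb.key] = emb
    embeddings = sorted(seen.values())
    out = {"F1": len(embeddings), "F2": 0, "F3": 0}
    for measure in (Measure.F2, Measure.F3):
        ec = EquivalenceClass(pattern=pat, all_embeddings=list(embeddings))
        if embeddings:
            count_frequency(g, ec, measure)
        out[measure.value] = ec.f_disjoint
    return out
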