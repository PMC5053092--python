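"""Join-based discovery: growth, classification, pruning, reporting."""

import json

import pytest

from motifdisc import (DiscoveryConfig, Embedding, Measure, NetworkGraph,
                       Pattern, are_isomorphic, classify, connected,
                       count_pattern, find_motifs, join_pair, run_iteration)
from motifdisc.join_engine import seed_basic_classes
from tests.conftest import S1_EDGES


def two_five_cycles() -> NetworkGraph:
    g = NetworkGraph()
    for i in range(5):
        g.add_edge(f"x{i}", f"x{(i + 1) % 5}")
        g.add_edge(f"y{i}", f"y{(i + 1) % 5}")
    return g


class TestJoinPair:
    def test_overlapping_instances_join(self):
        tri = Embedding([("a", "b"), ("a", "c"), ("b", "c")])
        m1 = Embedding([("b", "c"), ("b", "e")])
        joined = join_pair(tri, m1)
        assert joined is not None
        assert joined.edge_set == Embedding(S1_EDGES).edge_set

    def test_disjoint_instances_do_not_join(self):
        a = Embedding([("a", "b"), ("b", "c")])
        b = Embedding([("x", "y"), ("y", "z")])
        assert join_pair(a, b) is None

    def test_contained_instance_does_not_grow(self):
        tri = Embedding([("a", "b"), ("a", "c"), ("b", "c")])
        m1 = Embedding([("a", "b"), ("a", "c")])
        assert join_pair(tri, m1) is None


class TestRunIteration:
    def test_first_iteration_finds_triangle_pendant(self, fig1):
        cfg = DiscoveryConfig(mu=4, alpha=1, size_mode="edges")
        basics = seed_basic_classes(fig1, cfg)
        out = run_iteration(fig1, basics, basics, cfg)
        target = Pattern(S1_EDGES)
        match = [ec for ec in out if classify(ec.pattern, [target]) == 0]
        assert len(match) == 1
        assert match[0].f_disjoint == 2

    def test_alpha_above_everything_prunes_all(self, fig1):
        cfg = DiscoveryConfig(mu=4, alpha=100, size_mode="edges")
        basics = seed_basic_classes(fig1, DiscoveryConfig(mu=4, alpha=1,
                                                          size_mode="edges"))
        assert run_iteration(fig1, basics, basics, cfg) == []

    def test_no_duplicate_instances_after_joins(self, fig1):
        cfg = DiscoveryConfig(mu=4, alpha=1, size_mode="edges")
        basics = seed_basic_classes(fig1, cfg)
        for ec in run_iteration(fig1, basics, basics, cfg):
            keys = [e.key for e in ec.all_embeddings]
            assert len(keys) == len(set(keys))


class TestFindMotifs:
    def test_worked_example_frequent_four_edge_motif(self, fig1):
        report = find_motifs(fig1, DiscoveryConfig(mu=4, alpha=2,
                                                   size_mode="edges"))
        matches = [r for r in report.records
                   if are_isomorphic([(str(u), str(v)) for u, v in r.pattern_edges],
                                     S1_EDGES)]
        assert len(matches) == 1
        assert matches[0].frequency == 2

    def test_alpha_three_excludes_it(self, fig1):
        report = find_motifs(fig1, DiscoveryConfig(mu=4, alpha=3,
                                                   size_mode="edges"))
        assert report.records == []

    def test_two_disjoint_five_cycles(self):
        g = two_five_cycles()
        report = find_motifs(g, DiscoveryConfig(mu=5, alpha=2,
                                                size_mode="nodes",
                                                join_source="all"))
        cycle = [("c0", "c1"), ("c1", "c2"), ("c2", "c3"), ("c3", "c4"),
                 ("c0", "c4")]
        matches = [r for r in report.records
                   if are_isomorphic([(str(u), str(v)) for u, v in r.pattern_edges],
                                     cycle)]
        assert len(matches) == 1
        assert matches[0].frequency == 2

    def test_reported_motifs_are_sound(self, fig1):
        for measure in Measure:
            report = find_motifs(fig1, DiscoveryConfig(mu=4, alpha=1,
                                                       size_mode="nodes",
                                                       measure=measure))
            assert report.records
            host_edges = fig1.edges
            for rec in report.records:
                pat = [(str(u), str(v)) for u, v in rec.pattern_edges]
                used_edges, used_nodes = set(), set()
                for emb in rec.embeddings:
                    eset = {tuple(sorted(e)) for e in emb}
                    assert eset <= host_edges
                    assert connected(eset)
                    assert are_isomorphic(eset, pat)
                    nodes = {n for e in eset for n in e}
                    if measure is Measure.F2:
                        assert not used_edges & eset
                    else:
                        assert not used_nodes & nodes
                    used_edges |= eset
                    used_nodes |= nodes
                # anti-frequency-inflation
                if measure is Measure.F2:
                    assert rec.frequency * rec.n_edges <= fig1.number_of_edges()
                else:
                    assert rec.frequency * rec.n_nodes <= fig1.number_of_nodes()

    def test_deterministic_output(self, fig1):
        cfg = dict(mu=4, alpha=1, size_mode="nodes")
        r1 = find_motifs(fig1, DiscoveryConfig(**cfg))
        r2 = find_motifs(fig1, DiscoveryConfig(**cfg))
        assert r1.to_json() == r2.to_json()


class TestConfigValidation:
    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            DiscoveryConfig(mu=4, alpha=0)

    @pytest.mark.parametrize("mu,mode", [(2, "nodes"), (1, "edges")])
    def test_mu_below_basic_patterns(self, mu, mode):
        with pytest.raises(ValueError):
            DiscoveryConfig(mu=mu, size_mode=mode)


class TestCountPattern:
    def test_worked_example_counts(self, fig1):
        assert count_pattern(fig1, S1_EDGES) == {"F1": 3, "F2": 2, "F3": 1}

    def test_absent_pattern(self, fig1):
        star4 = [("c", "w"), ("c", "x"), ("c", "y"), ("c", "z"), ("c", "q")]
        assert count_pattern(fig1, star4) == {"F1": 0, "F2": 0, "F3": 0}

    def test_report_serialization(self, fig1):
        report = find_motifs(fig1, DiscoveryConfig(mu=4, alpha=2,
                                                   size_mode="edges"))
        payload = json.loads(report.to_json())
        assert payload["config"]["alpha"] == 2
        assert payload["motifs"][0]["frequency"] == 2
        tsv = report.to_tsv()
        assert tsv.splitlines()[0].startswith("pattern_id")
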