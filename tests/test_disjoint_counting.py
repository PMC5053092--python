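"""Overlap graphs, greedy MIS, and disjoint frequencies."""

import random

import pytest

from motifdisc import (BasicPattern, Embedding, EquivalenceClass, Measure,
                       Pattern, build_overlap_graph, count_frequency,
                       enumerate_basic, greedy_mis, greedy_mis_algebraic)
from motifdisc.synthetic_data import BAConfig, barabasi_albert
from tests.conftest import exact_mis_size


class TestBuildOverlapGraph:
    def test_edge_overlap_graph_is_a_path(self, fig1c_embeddings):
        # S1-S3 share (b,e); S2-S3 share the second triangle; S1, S2 disjoint
        og = build_overlap_graph(fig1c_embeddings, Measure.F2)
        assert og.adjacency == {0: {2}, 1: {2}, 2: {0, 1}}

    def test_node_overlap_graph_is_a_triangle(self, fig1c_embeddings):
        og = build_overlap_graph(fig1c_embeddings, Measure.F3)
        assert og.adjacency == {0: {1, 2}, 1: {0, 2}, 2: {0, 1}}

    def test_single_embedding(self, fig1c_embeddings):
        og = build_overlap_graph(fig1c_embeddings[:1], Measure.F2)
        assert og.adjacency == {0: set()}

    def test_duplicates_rejected(self, fig1c_embeddings):
        with pytest.raises(ValueError):
            build_overlap_graph([fig1c_embeddings[0]] * 2)


class TestGreedyMis:
    def test_edge_disjoint_pair_selected(self, fig1c_embeddings):
        og = build_overlap_graph(fig1c_embeddings, Measure.F2)
        assert greedy_mis(og) == {0, 1}  # {S1, S2}

    def test_node_disjoint_single(self, fig1c_embeddings):
        og = build_overlap_graph(fig1c_embeddings, Measure.F3)
        assert len(greedy_mis(og)) == 1

    def test_edgeless_overlap_graph_keeps_everything(self):
        embs = [Embedding([(f"a{i}", f"b{i}"), (f"b{i}", f"c{i}")]) for i in range(4)]
        og = build_overlap_graph(embs, Measure.F2)
        assert greedy_mis(og) == {0, 1, 2, 3}


class TestGreedyMisAlgebraic:
    def test_four_disjoint_two_paths_in_worked_example(self, fig1):
        # exhaustive search shows the best edge-disjoint packing of 2-paths
        # over the eight host edges has size 4
        embs = enumerate_basic(fig1, BasicPattern.M1)
        chosen = greedy_mis_algebraic(fig1, embs, BasicPattern.M1, Measure.F2)
        assert len(chosen) == 4
        assert len(chosen) == exact_mis_size(embs, Measure.F2)

    def test_both_triangles_selected(self, fig1):
        embs = enumerate_basic(fig1, BasicPattern.M2)
        chosen = greedy_mis_algebraic(fig1, embs, BasicPattern.M2, Measure.F2)
        assert chosen == {0, 1}

    def test_brute_force_switch_agrees(self, fig1):
        embs = enumerate_basic(fig1, BasicPattern.M4)
        for measure in Measure:
            fast = greedy_mis_algebraic(fig1, embs, BasicPattern.M4, measure)
            slow = greedy_mis_algebraic(fig1, embs, BasicPattern.M4, measure,
                                        brute_force=True)
            assert fast == slow

    @pytest.mark.parametrize("seed", range(6))
    def test_independent_maximal_and_bounded_by_optimum(self, seed):
        g = barabasi_albert(BAConfig(n_nodes=14, density=1, seed=seed))
        for pid in BasicPattern:
            embs = enumerate_basic(g, pid)
            if not embs:
                continue
            for measure in Measure:
                chosen = greedy_mis_algebraic(g, embs, pid, measure)
                # independence
                items = [embs[i].edge_set if measure is Measure.F2
                         else embs[i].node_set for i in sorted(chosen)]
                for i in range(len(items)):
                    for j in range(i + 1, len(items)):
                        assert not (items[i] & items[j])
                # maximality
                used = frozenset().union(*items) if items else frozenset()
                for k, e in enumerate(embs):
                    if k not in chosen:
                        probe = e.edge_set if measure is Measure.F2 else e.node_set
                        assert used & probe
                if len(embs) <= 18:
                    assert len(chosen) <= exact_mis_size(embs, measure)


class TestCountFrequency:
    def test_triangle_pendant_pattern_f2(self, fig1, fig1c_embeddings):
        ec = EquivalenceClass(pattern=Pattern(fig1c_embeddings[0].edge_set),
                              all_embeddings=list(fig1c_embeddings))
        assert count_frequency(fig1, ec, Measure.F2) == 2
        assert ec.f1 == 3
        assert [e.key for e in ec.disjoint_embeddings] == sorted(
            [fig1c_embeddings[0].key, fig1c_embeddings[1].key])

    def test_triangle_pattern_f3(self, fig1):
        embs = enumerate_basic(fig1, BasicPattern.M2)
        ec = EquivalenceClass(pattern=Pattern(embs[0].edge_set),
                              all_embeddings=list(embs),
                              basic_id=BasicPattern.M2)
        # node sets {a,b,c} and {e,f,g} are disjoint
        assert count_frequency(fig1, ec, Measure.F3) == 2

    def test_five_edge_pattern_has_one_copy(self, fig1):
        emb = Embedding([("b", "e"), ("e", "d"), ("e", "f"), ("f", "g"), ("e", "g")])
        ec = EquivalenceClass(pattern=Pattern(emb.edge_set), all_embeddings=[emb])
        assert count_frequency(fig1, ec, Measure.F2) == 1

    def test_frequency_ordering_f1_f2_f3(self, fig1, fig1c_embeddings):
        counts = {}
        for measure in Measure:
            ec = EquivalenceClass(pattern=Pattern(fig1c_embeddings[0].edge_set),
                                  all_embeddings=list(fig1c_embeddings))
            counts[measure] = count_frequency(fig1, ec, measure)
        assert 3 >= counts[Measure.F2] >= counts[Measure.F3]
        assert counts[Measure.F2] == 2 and counts[Measure.F3] == 1
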