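"""Exhaustive oracle, greedy variants, additive comparator."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from nomas.baselines import (GeneScore, additive_search,
                             enumerate_connected_subgraphs, exhaustive_search,
                             greedy_grow, greedy_search, single_gene_pvalues)
from nomas.core import Instance
from nomas.survival import montecarlo_pvalue, score_w

from test_core import make_instance, oracle_w


class TestEnumeration:
    def test_path(self):
        g = nx.path_graph(["a", "b", "c"])
        assert set(enumerate_connected_subgraphs(g, 2)) == {
            frozenset("ab"), frozenset("bc")}
        assert set(enumerate_connected_subgraphs(g, 3)) == {frozenset("abc")}

    def test_star(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        sets = list(enumerate_connected_subgraphs(g, 3))
        assert len(sets) == 6  # center + any 2 of 4 leaves
        assert len(set(sets)) == 6
        assert all(0 in s for s in sets)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_completeness_vs_brute_force(self, seed, k):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(1 << 30)))
        enum = set(enumerate_connected_subgraphs(g, k))
        brute = {frozenset(c) for c in itertools.combinations(g.nodes(), k)
                 if nx.is_connected(g.subgraph(c))}
        assert enum == brute

    def test_k_exceeds_graph(self):
        g = nx.path_graph(3)
        assert list(enumerate_connected_subgraphs(g, 5)) == []


class TestExhaustive:
    def test_single_mutated_triple(self):
        inst = make_instance(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")],
            {"a": [0, 1], "b": [2], "c": [3]}, m=16)
        sol = exhaustive_search(inst, None, None, 3, "reduced")
        assert sol.genes == ("a", "b", "c")

    def test_k1_is_best_single_gene(self, null_instance):
        sol = exhaustive_search(null_instance, None, None, 1, "reduced")
        best = max(null_instance.nodes, key=lambda g: (oracle_w(
            null_instance, [g])))
        assert sol.genes == (best,)

    def test_matches_subset_filter_oracle(self, null_instance):
        """Independent oracle: filter all C(n,k) subsets for connectivity and
        maximize the survival-module score."""
        inst = null_instance
        best = max(
            (oracle_w(inst, trip), tuple(sorted(trip)))
            for trip in itertools.combinations(inst.nodes, 3)
            if nx.is_connected(inst.graph.subgraph(trip)))
        sol = exhaustive_search(inst, None, None, 3, "reduced")
        assert sol.w == pytest.approx(best[0], abs=1e-9)


def connector_instance():
    """Two high-signal genes g1, g2 joined by an unmutated connector c,
    each with a tempting decoy neighbor (d1, d2).  All 8 samples are events.
    Hand-computed scores: w({g1})=0.4640, w({g1,d1})=0.5608,
    w(optimum {c,g1,g2})=0.6343."""
    return make_instance(
        [("g1", "c"), ("c", "g2"), ("g1", "d1"), ("g2", "d2")],
        {"g1": [0, 1], "g2": [2, 3], "d1": [2], "d2": [0]}, m=8)


class TestGreedy:
    def test_monotone_instance_found_by_all_variants(self):
        inst = make_instance([("a", "b"), ("b", "c"), ("c", "d")],
                             {"a": [0, 1], "b": [2, 3], "c": [4, 5]}, m=20)
        for variant in ("G1", "G2", "G3"):
            sol = greedy_search(inst, None, None, 3, variant, "reduced")
            assert sol.genes == ("a", "b", "c"), variant

    def test_never_beats_exhaustive(self, null_instance):
        ex = exhaustive_search(null_instance, None, None, 3, "reduced")
        for variant in ("G1", "G2", "G3"):
            gr = greedy_search(null_instance, None, None, 3, variant,
                               "reduced")
            assert gr.w <= ex.w + 1e-9

    def test_connector_defeats_g1_from_signal_starts(self):
        """From the high-signal seeds, G1 is lured to the decoys; G2 sees the
        distance-2 partner through the connector and G3's lookahead values
        the zero-gain connector step — both recover the optimum."""
        inst = connector_instance()
        opt = exhaustive_search(inst, None, None, 3, "reduced")
        assert opt.genes == ("c", "g1", "g2")
        assert opt.w == pytest.approx(0.63452, abs=1e-4)
        for start in ("g1", "g2"):
            g1_sol = greedy_grow(inst, start, 3, "G1", "reduced")
            assert g1_sol.w < opt.w - 1e-6, f"G1 from {start}"
            for variant in ("G2", "G3"):
                sol = greedy_grow(inst, start, 3, variant, "reduced")
                assert sol.genes == opt.genes, f"{variant} from {start}"

    def test_invalid_variant(self, null_instance):
        with pytest.raises(ValueError, match="variant"):
            greedy_search(null_instance, None, None, 3, "G9", "reduced")


class TestSingleGenePvalues:
    def test_unmutated_gene(self):
        inst = make_instance([("a", "b")], {"a": [0, 1]}, m=10)
        scores = {s.gene: s for s in
                  single_gene_pvalues(inst.matrix, inst.survival)}
        assert scores["b"].pvalue == 1.0 and scores["b"].sign == 0

    def test_pvalue_bounds_and_direction(self, null_instance):
        for s in single_gene_pvalues(null_instance.matrix,
                                     null_instance.survival):
            assert 0 < s.pvalue <= 1
            if s.sign != 0:
                assert s.additive == pytest.approx(-np.log10(s.pvalue))

    def test_asymptotic_matches_montecarlo(self):
        """At m=200 the normal-tail p agrees with the Monte-Carlo estimate."""
        rng = np.random.default_rng(5)
        from nomas.survival import SurvivalData
        c = (rng.random(200) < 0.5).astype(np.uint8)
        s = SurvivalData(m=200, order=np.arange(200), c=c,
                         raw_times=np.arange(1.0, 201.0))
        x = np.zeros(200, np.uint8)
        x[rng.choice(200, 50, replace=False)] = 1
        dec = score_w(x, s)
        p_asym = float(stats.norm.sf(abs(dec.normalized)))
        tail = "upper" if dec.normalized > 0 else "lower"
        p_mc = montecarlo_pvalue(x, s, B=20_000, tail=tail, seed=6)
        assert abs(p_asym - p_mc) < 0.02


class TestAdditiveSearch:
    def test_equal_scores_any_connected_set(self, small_graph):
        scores = [GeneScore(gene=g, pvalue=0.01, sign=1, additive=2.0)
                  for g in small_graph.nodes()]
        sols = additive_search(small_graph, scores, 3, "reduced", L=30,
                               seed=1)
        assert sols
        assert sols[0].a_score == pytest.approx(6.0)
        assert nx.is_connected(small_graph.subgraph(sols[0].genes))

    def test_matches_enumeration_optimum(self, null_instance):
        """Additive DP equals the enumerated optimum of a(S) on the
        direction partition (the additive score is exact per coloring)."""
        inst = null_instance
        scores = single_gene_pvalues(inst.matrix, inst.survival)
        add = {s.gene: s.additive for s in scores if s.sign == 1}
        sub = inst.graph.subgraph(add)
        best = max((sum(add[g] for g in trip)
                    for trip in itertools.combinations(sub.nodes(), 3)
                    if nx.is_connected(sub.subgraph(trip))), default=None)
        assert best is not None
        sols = additive_search(inst.graph, scores, 3, "reduced", L=80, seed=2)
        assert sols[0].a_score == pytest.approx(best, abs=1e-9)

    def test_partition_too_small(self):
        inst = make_instance([("a", "b"), ("b", "c")], {"a": [0, 1]}, m=10)
        scores = single_gene_pvalues(inst.matrix, inst.survival)
        with pytest.warns(UserWarning, match="partition"):
            sols = additive_search(inst.graph, scores, 3, "increased", L=5)
        assert sols == []
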