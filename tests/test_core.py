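"""Color-coding DP: table rules, oracle dominance, determinism, work bound."""

import itertools

import networkx as nx
import numpy as np
import pytest

from nomas.core import (Coloring, Instance, RunConfig, color_graph,
                        fill_table, init_table, iterations_for, parallel_fill,
                        run_nomas)
from nomas.data_io import MutationMatrix
from nomas.survival import gene_set_indicator, rank_samples, score_w


def make_instance(edges, rows, m, censor=None):
    """Tiny instance from an edge list and per-gene mutated-sample lists
    (sample j has survival time j+1; all events unless censor given)."""
    g = nx.Graph(edges)
    genes = sorted(g.nodes())
    M = np.zeros((len(genes), m), dtype=np.uint8)
    for i, gene in enumerate(genes):
        for j in rows.get(gene, []):
            M[i, j] = 1
    matrix = MutationMatrix(genes, [f"s{j}" for j in range(m)], M)
    censor = np.ones(m, int) if censor is None else np.asarray(censor)
    surv = rank_samples(np.arange(1.0, m + 1), censor)
    return Instance(g, matrix, surv)


def oracle_w(inst, genes):
    """Score a gene set via the survival-module route (independent of the
    packed-bitset path used inside the DP)."""
    x = gene_set_indicator(inst.matrix, genes, inst.survival)
    return score_w(x, inst.survival).w


class TestColoring:
    def test_k1_single_color(self, null_instance):
        col = color_graph(null_instance, 1, seed=0)
        assert (col.colors == 0).all()

    def test_deterministic_given_seed(self, null_instance):
        a = color_graph(null_instance, 4, seed=9)
        b = color_graph(null_instance, 4, seed=9)
        assert (a.colors == b.colors).all()

    def test_colorful_fraction(self, null_instance):
        """A fixed triple is colorful in ~k!/k^k = 6/27 of random colorings."""
        tri = [0, 1, 2]
        hits = 0
        n_draws = 20_000
        for i in range(n_draws):
            col = color_graph(null_instance, 3, seed=[5, i])
            hits += len({int(col.colors[v]) for v in tri}) == 3
        assert abs(hits / n_draws - 6 / 27) < 0.01

    def test_invalid_k(self, null_instance):
        with pytest.raises(ValueError):
            color_graph(null_instance, 0, seed=1)


class TestInitTable:
    def test_singleton_rule(self):
        inst = make_instance([("a", "b"), ("b", "c")],
                             {"a": [0], "b": [1], "c": [2]}, m=4)
        col = Coloring(k=3, colors=np.array([1, 0, 2]))  # a->2, b->1, c->3
        t = init_table(inst, col)
        assert t.entry(0b010, "a") == ("a",)
        assert t.entry(0b001, "a") is None
        assert int(t.present.sum()) == inst.n


class TestFillTable:
    def test_unique_colorful_path(self):
        """Path a-b-c colored 1,2,3: the only full-colorset entry at b is
        the whole path."""
        inst = make_instance([("a", "b"), ("b", "c")],
                             {"a": [0], "b": [1], "c": [2]}, m=4)
        col = Coloring(k=3, colors=np.array([0, 1, 2]))
        t = fill_table(init_table(inst, col))
        assert t.entry(0b111, "b") == ("a", "b", "c")

    def test_non_colorful_triangle_has_no_full_entry(self):
        inst = make_instance([("a", "b"), ("b", "c"), ("a", "c")],
                             {"a": [0], "b": [1], "c": [2]}, m=4)
        col = Coloring(k=3, colors=np.array([0, 1, 1]))
        t = fill_table(init_table(inst, col))
        assert all(t.entry(0b111, g) is None for g in "abc")

    def test_entries_bounded_by_colorful_optimum(self, null_instance):
        """No stored full-row entry beats the best colorful connected triple
        (brute-force enumeration under the same coloring); equality is not
        required — the non-additive score admits merge failures."""
        inst = null_instance
        col = color_graph(inst, 3, seed=77)
        t = fill_table(init_table(inst, col))
        best = -np.inf
        for trip in itertools.combinations(inst.nodes, 3):
            if not nx.is_connected(inst.graph.subgraph(trip)):
                continue
            if len({int(col.colors[inst.node_index[g]]) for g in trip}) < 3:
                continue
            best = max(best, oracle_w(inst, trip))
        for sol in t.full_row_solutions():
            assert sol.w <= best + 1e-9

    def test_work_bound(self, null_instance):
        """Candidate evaluations per iteration are within the O(|E| 4^k)
        combination budget (the m factor is per-evaluation cost)."""
        k = 3
        col = color_graph(null_instance, k, seed=3)
        t = fill_table(init_table(null_instance, col))
        assert t.n_candidates <= null_instance.graph.number_of_edges() * 4**k


class TestParallelFill:
    def test_threads_match_serial(self, null_instance):
        col = color_graph(null_instance, 4, seed=12)
        t1 = fill_table(init_table(null_instance, col), threads=1)
        t4 = parallel_fill(init_table(null_instance, col), threads=4)
        assert (t1.present == t4.present).all()
        assert (t1.verts == t4.verts).all()
        np.testing.assert_array_equal(t1.entV, t4.entV)

    def test_threads_clamped(self, null_instance):
        col = color_graph(null_instance, 2, seed=1)
        with pytest.warns(UserWarning, match="clamped"):
            fill_table(init_table(null_instance, col),
                       threads=null_instance.n + 5)


class TestRunNomas:
    def test_dominant_planted_triple(self):
        """With a single mutated connected triple and no other signal, that
        triple is the rank-1 solution."""
        inst = make_instance(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")],
            {"a": [0, 1], "b": [2, 3], "c": [4]}, m=20)
        res = run_nomas(inst, config=RunConfig(k=3, L=30, seed=4,
                                               directions=("reduced",)))
        assert res["reduced"][0].genes == ("a", "b", "c")

    def test_deterministic_given_seed(self, null_instance):
        cfg = RunConfig(k=3, L=10, seed=21)
        r1 = run_nomas(null_instance, config=cfg)
        r2 = run_nomas(null_instance, config=cfg)
        for d in cfg.directions:
            assert [s.genes for s in r1[d]] == [s.genes for s in r2[d]]
            assert [s.w for s in r1[d]] == [s.w for s in r2[d]]

    def test_soundness_of_reported_solutions(self, null_instance):
        """Every reported set is connected, has k genes, and its stored score
        matches an independent recomputation."""
        res = run_nomas(null_instance, config=RunConfig(k=3, L=20, seed=8))
        for d, sols in res.items():
            assert sols
            for s in sols:
                assert len(s.genes) == 3
                assert nx.is_connected(null_instance.graph.subgraph(s.genes))
                assert s.w == pytest.approx(oracle_w(null_instance, s.genes),
                                            abs=1e-9)

    def test_monotone_benefit_of_iterations(self, null_instance):
        """Best score over L colorings is non-decreasing in L (shared seed:
        the first L' colorings of a longer run are identical)."""
        best = []
        for L in (2, 5, 15):
            r = run_nomas(null_instance,
                          config=RunConfig(k=3, L=L, seed=33,
                                           directions=("reduced",)))
            best.append(r["reduced"][0].adjusted)
        assert best[0] <= best[1] <= best[2]

    def test_increased_direction_sign(self):
        """Mutations concentrated in long survivors give normalized < 0."""
        inst = make_instance([("a", "b"), ("b", "c")],
                             {"a": [16, 17], "b": [18, 19]}, m=20)
        res = run_nomas(inst, config=RunConfig(k=2, L=20, seed=2,
                                               directions=("increased",)))
        top = res["increased"][0]
        assert top.normalized < 0

    def test_k_larger_than_graph(self, null_instance):
        with pytest.raises(ValueError, match="exceeds"):
            run_nomas(null_instance, config=RunConfig(k=100, L=1))

    def test_no_mutations_rejected(self):
        inst = make_instance([("a", "b")], {}, m=4)
        with pytest.raises(ValueError, match="no mutated genes"):
            run_nomas(inst, config=RunConfig(k=2, L=1))


def test_iterations_for_failure_probability():
    # ceil(ln(1/delta) e^k)
    assert iterations_for(3, 0.05) == int(np.ceil(np.log(20) * np.e**3))
    with pytest.raises(ValueError):
        iterations_for(3, 1.5)
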