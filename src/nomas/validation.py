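"""Desk-scale validation experiments.

Self-contained experiments that exercise the whole pipeline on simulated
data and return summary numbers.  They serve two purposes: the test suite
asserts their qualitative outcomes, and ``scripts/acceptance.py`` reports
their values for reproduction.  Problem sizes are chosen so the full set
runs in minutes on one core; docs/methods.md discusses what these scales
do and do not probe.

All randomness is controlled by a single ``seed`` argument per experiment.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from .baselines import (additive_search, exhaustive_search, greedy_search,
                        single_gene_pvalues)
from .core import Instance, RunConfig, run_nomas
from .significance import greedy_searcher, permutation_test
from .simulate import PlantedModelConfig, null_model, planted_model, random_graph
from .survival import (SurvivalData, montecarlo_pvalue, null_statistics,
                       score_w)

__all__ = [
    "worked_example",
    "null_calibration",
    "oracle_agreement",
    "planted_recovery",
    "permutation_calibration",
    "score_hierarchy",
]


def worked_example() -> dict:
    """The fully hand-checkable 4-sample instance plus a 6-sample
    Monte-Carlo-vs-enumeration comparison.

    Four samples, all events, population x = (1,0,1,0) gives
    V = 1/2 - 1/3 + 1/2 = 2/3 and normalized statistic ~0.834; at m=6 the
    null has only C(6,3) = 20 labelings, so the Monte-Carlo p-value can be
    compared against exact enumeration.
    """
    s4 = SurvivalData(m=4, order=np.arange(4), c=np.ones(4, np.uint8),
                      raw_times=np.arange(1.0, 5.0))
    dec = score_w(np.array([1, 0, 1, 0]), s4)

    s6 = SurvivalData(m=6, order=np.arange(6), c=np.ones(6, np.uint8),
                      raw_times=np.arange(1.0, 7.0))
    x_obs = np.array([1, 1, 0, 1, 0, 0])
    obs = score_w(x_obs, s6).normalized
    ge = sum(score_w(np.isin(np.arange(6), ones).astype(int), s6).normalized
             >= obs - 1e-12
             for ones in itertools.combinations(range(6), 3))
    p_exact = ge / 20
    p_mc = montecarlo_pvalue(x_obs, s6, B=100_000, tail="upper", seed=0)
    return {
        "V": dec.V,
        "f_c": dec.f_c,
        "w": dec.w,
        "normalized": dec.normalized,
        "p_exact_m6": p_exact,
        "p_mc_m6": p_mc,
        "mc_enum_abs_diff": abs(p_mc - p_exact),
    }


def null_calibration(m: int = 200, m1: int = 60, B: int = 100_000,
                     event_frac: float = 0.5, seed: int = 0) -> dict:
    """KS comparison of the fixed-m1 null statistic against N(0,1).

    The permutation variance of V equals sigma^2(x,c) exactly, so the
    normalized statistic should be standard normal up to O(1/sqrt(m))
    skewness.
    """
    rng = np.random.default_rng(seed)
    c = (rng.random(m) < event_frac).astype(np.uint8)
    s = SurvivalData(m=m, order=np.arange(m), c=c,
                     raw_times=np.arange(1.0, m + 1.0))
    draws = null_statistics(s, m1, B, seed=rng)
    ks = stats.kstest(draws, "norm")
    return {"ks_stat": float(ks.statistic), "ks_pvalue": float(ks.pvalue),
            "mean": float(draws.mean()), "std": float(draws.std()), "B": B}


def oracle_agreement(n_instances: int = 100, seed: int = 0) -> dict:
    """NoMAS vs exhaustive enumeration on small random instances.

    Connected Erdős–Rényi graphs (n=25, mean degree 4), m=40 samples with a
    flat 10% background mutation rate and no planted signal, k=3, L=100
    colorings.  Counts exact score agreement and (should-be-impossible)
    excesses over the enumerated optimum.
    """
    eq = exceed = 0
    for i in range(n_instances):
        g = random_graph(25, 4.0, seed=[seed, 2 * i])
        ds = null_model(g, m=40, background_rate=0.1, seed=[seed, 2 * i + 1])
        inst = Instance(ds.graph, ds.matrix, ds.survival)
        nom = run_nomas(inst, config=RunConfig(
            k=3, L=100, seed=i + seed, directions=("reduced",),
            top_n=1))["reduced"][0].w
        ex = exhaustive_search(inst, None, None, 3, "reduced").w
        if nom > ex + 1e-9:
            exceed += 1
        elif abs(nom - ex) <= 1e-9:
            eq += 1
    return {"n": n_instances, "agree": eq, "exceed": exceed,
            "agreement_rate": eq / n_instances}


def planted_recovery(n_reps: int = 25, n: int = 500, avg_degree: float = 8.0,
                     k: int = 5, p: float = 0.85, m: int = 1000, L: int = 64,
                     seed: int = 0) -> dict:
    """Recovery of the planted subnetwork D as the rank-1 solution.

    Mirrors the planted-model benchmark at reduced scale: for each
    replicate a fresh graph and dataset are drawn and NoMAS is run with L
    colorings; reports how often rank-1 equals D exactly and the mean
    fraction of D's genes contained in the rank-1 solution.
    """
    hits = 0
    fractions = []
    for r in range(n_reps):
        g = random_graph(n, avg_degree, seed=[seed, 3 * r])
        ds = planted_model(g, PlantedModelConfig(
            k=k, p=p, m=m, seed=[seed, 3 * r + 1]))
        inst = Instance(ds.graph, ds.matrix, ds.survival)
        top = run_nomas(inst, config=RunConfig(
            k=k, L=L, seed=r + seed, directions=("reduced",),
            top_n=1))["reduced"][0]
        planted = set(ds.planted)
        hits += set(top.genes) == planted
        fractions.append(len(set(top.genes) & planted) / k)
    return {"n": n_reps, "recovered": hits, "recovery_rate": hits / n_reps,
            "mean_planted_fraction": float(np.mean(fractions))}


def permutation_calibration(n_datasets: int = 50, n: int = 150,
                            avg_degree: float = 8.0, m: int = 60, k: int = 4,
                            L: int = 64, n_perm: int = 30,
                            seed: int = 0) -> dict:
    """Permutation-test behavior on signal-free datasets.

    Each dataset has heavy-tailed background mutations independent of
    survival.  The rank-1 permutation p-value is computed twice on the same
    permuted matrices: with NoMAS (matched L) and with greedy G1 as the
    search on permuted data.  Under the null the NoMAS p-values should be
    calibrated (not anti-conservative); the greedy-based p-values should
    be stochastically smaller, since greedy finds lower scores on the
    permuted data and therefore understates how extreme the observed score
    is.
    """
    p_nomas, p_greedy = [], []
    for d in range(n_datasets):
        g = random_graph(n, avg_degree, seed=[seed, 3 * d])
        ds = planted_model(g, PlantedModelConfig(
            k=1, p=0.0, passenger_rate=0.0, m=m, seed=[seed, 3 * d + 1]))
        cfg = RunConfig(k=k, L=L, seed=d + seed, directions=("reduced",),
                        top_n=1)
        inst = Instance(ds.graph, ds.matrix, ds.survival)
        obs = run_nomas(inst, config=cfg)
        common = dict(n_perm=n_perm, L_perm=L, seed=d + seed + 1,
                      observed=obs)
        rn = permutation_test(ds.graph, ds.matrix, ds.survival, cfg, **common)
        rg = permutation_test(ds.graph, ds.matrix, ds.survival, cfg,
                              searcher=greedy_searcher("G1"), **common)
        p_nomas.append(float(rn["reduced"].pvalues[0]))
        p_greedy.append(float(rg["reduced"].pvalues[0]))
    p_n = np.asarray(p_nomas)
    p_g = np.asarray(p_greedy)
    ks = stats.kstest(p_n, "uniform", alternative="greater")
    return {
        "n": n_datasets,
        "ks_anticons_pvalue": float(ks.pvalue),
        "mean_p_nomas": float(p_n.mean()),
        "mean_p_greedy": float(p_g.mean()),
        "n_greedy_smaller": int(np.sum(p_g < p_n)),
        "n_greedy_larger": int(np.sum(p_g > p_n)),
    }


def score_hierarchy(n_reps: int = 5, n: int = 60, avg_degree: float = 6.0,
                    k: int = 4, p: float = 0.85, m: int = 200, L: int = 100,
                    seed: int = 0) -> dict:
    """greedy <= NoMAS <= exhaustive, and additive optimum <= NoMAS, in w.

    On planted instances small enough for exhaustive enumeration, checks
    the expected ordering of the four search strategies' best scores
    (greedy = best of G1/G2/G3).  The additive comparator optimizes
    a(S) = sum of -log10 single-gene p-values on the reduced-survival
    partition; its optimum is then re-scored with w.
    """
    violations = 0
    additive_violations = 0
    for r in range(n_reps):
        g = random_graph(n, avg_degree, seed=[seed, 3 * r])
        ds = planted_model(g, PlantedModelConfig(
            k=k, p=p, m=m, seed=[seed, 3 * r + 1]))
        inst = Instance(ds.graph, ds.matrix, ds.survival)
        ex = exhaustive_search(inst, None, None, k, "reduced").w
        nom = run_nomas(inst, config=RunConfig(
            k=k, L=L, seed=r + seed, directions=("reduced",),
            top_n=1))["reduced"][0].w
        gr = max(greedy_search(inst, None, None, k, v, "reduced").w
                 for v in ("G1", "G2", "G3"))
        if not (gr <= nom + 1e-9 and nom <= ex + 1e-9):
            violations += 1
        sols = additive_search(ds.graph,
                               single_gene_pvalues(ds.matrix, ds.survival),
                               k, "reduced", L=64, seed=r + seed)
        add_w = inst.score_set(sols[0].genes)[0] if sols else -np.inf
        if add_w > nom + 1e-9:
            additive_violations += 1
    return {"n": n_reps, "violations": violations,
            "additive_violations": additive_violations}
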