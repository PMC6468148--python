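"""Permutation testing and the survival-stratified holdout scheme.

Two complementary corrections for the selection performed by the search:

* the **permutation test** re-runs the search on datasets whose gene rows
  have been randomly re-assigned to gene labels (destroying the placement
  of mutations on the network while preserving each profile), and compares
  the rank-i observed score with the rank-i score on each permuted dataset;
* the **holdout scheme** splits the cohort into a training part (where
  subnetworks are discovered) and a holdout part (where their log-rank
  p-values are estimated by Monte Carlo), stratifying the split over g
  equal-width intervals of the observed time range so both parts retain
  the survival distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import RunConfig, run_nomas
from .data_io import MutationMatrix
from .survival import montecarlo_pvalue, rank_samples

__all__ = [
    "HoldoutSplit",
    "PermutationResult",
    "permute_rows",
    "permutation_test",
    "greedy_searcher",
    "holdout_split",
    "holdout_evaluate",
]


@dataclass(frozen=True)
class HoldoutSplit:
    """A survival-stratified partition of the cohort."""

    train_ids: tuple
    holdout_ids: tuple
    v: float
    g: int

    @property
    def m_t(self) -> int:
        return len(self.train_ids)

    @property
    def m_h(self) -> int:
        return len(self.holdout_ids)


@dataclass
class PermutationResult:
    """Rank-matched permutation p-values for one direction."""

    direction: str
    observed: list                # ScoredSubnetwork per rank
    observed_scores: np.ndarray   # direction-adjusted w per rank
    perm_scores: np.ndarray       # (n_perm, n_ranks), -inf where absent
    pvalues: np.ndarray
    n_perm: int

    def annotation(self, rank: int) -> str:
        if self.pvalues[rank] == 0.0:
            return f"< {1.0 / self.n_perm:g}"
        return ""


def permute_rows(matrix: MutationMatrix, seed=None) -> MutationMatrix:
    """Reassign gene mutation profiles to gene labels uniformly at random."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(matrix.n)
    return MutationMatrix(list(matrix.genes), list(matrix.samples),
                          matrix.M[perm])


def greedy_searcher(variant: str = "G1"):
    """Adapter: a greedy strategy with the searcher signature used by
    :func:`permutation_test` (returns rank lists per direction)."""
    from .baselines import greedy_search

    def search(graph, matrix, survival, config):
        out = {}
        for d in config.directions:
            try:
                sol = greedy_search(graph, matrix, survival, config.k,
                                    variant=variant, direction=d)
                out[d] = [sol]
            except ValueError:
                out[d] = []
        return out

    return search


def permutation_test(graph, matrix, survival, config: RunConfig,
                     n_perm: int = 100, L_perm: int = 32, seed: int = 0,
                     searcher=None, observed=None) -> dict:
    """Rank-i vs rank-i permutation test.

    ``searcher(graph, matrix, survival, config)`` is run on each row-permuted
    dataset (default: NoMAS itself with ``L_perm`` colorings); the p-value of
    the i-th observed solution is the fraction of permutations whose i-th
    best score meets or exceeds it.  Returns ``{direction: PermutationResult}``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if observed is None:
        observed = run_nomas(graph, matrix, survival, config=config)
    perm_cfg = replace(config, L=L_perm)
    results = {}
    n_ranks = {d: len(observed[d]) for d in config.directions}
    perm_scores = {d: np.full((n_perm, n_ranks[d]), -np.inf)
                   for d in config.directions}
    for b in range(n_perm):
        Mp = permute_rows(matrix, seed=[seed, b])
        cfg_b = replace(perm_cfg, seed=int((config.seed * 1009 + b + 1)
                                           % (2**31 - 1)))
        if searcher is None:
            sols = run_nomas(graph, Mp, survival, config=cfg_b)
        else:
            sols = searcher(graph, Mp, survival, cfg_b)
        for d in config.directions:
            for i, s in enumerate(sols.get(d, [])[: n_ranks[d]]):
                perm_scores[d][b, i] = s.adjusted
    for d in config.directions:
        obs = np.asarray([s.adjusted for s in observed[d]])
        pv = (perm_scores[d] >= obs[None, :]).mean(axis=0) if len(obs) else \
            np.empty(0)
        results[d] = PermutationResult(direction=d, observed=observed[d],
                                       observed_scores=obs,
                                       perm_scores=perm_scores[d],
                                       pvalues=pv, n_perm=n_perm)
    return results


def holdout_split(clinical: pd.DataFrame, v: float, g: int,
                  seed=None) -> HoldoutSplit:
    """Partition samples into training/holdout, stratified by survival time.

    The observed time range is cut into ``g`` equal-width intervals
    (last interval right-closed); within each interval a fraction v of the
    samples (floored) goes to training, uniformly at random.  Any global
    shortfall against m_t = floor(m*v) is distributed one sample at a time
    to the largest intervals, so the global training size is exactly m_t.
    """
    if not 0.0 < v < 1.0:
        raise ValueError("v must be in (0, 1)")
    if g < 1:
        raise ValueError("g must be >= 1")
    rng = np.random.default_rng(seed)
    ids = clinical["sample_id"].to_numpy()
    times = clinical["time"].to_numpy(dtype=float)
    m = len(ids)
    m_t = int(np.floor(m * v))
    lo, hi = times.min(), times.max()
    if hi == lo:
        bins = np.zeros(m, dtype=int)
    else:
        edges = np.linspace(lo, hi, g + 1)
        bins = np.clip(np.searchsorted(edges, times, side="right") - 1,
                       0, g - 1)
    members = [np.flatnonzero(bins == i) for i in range(g)]
    take = np.array([int(np.floor(len(mem) * v)) for mem in members])
    shortfall = m_t - take.sum()
    by_size = np.argsort([-len(mem) for mem in members], kind="stable")
    j = 0
    while shortfall > 0 and j < 10 * g:
        i = by_size[j % g]
        if take[i] < len(members[i]):
            take[i] += 1
            shortfall -= 1
        j += 1
    train_idx = []
    for i, mem in enumerate(members):
        if len(mem) == 0 or take[i] == 0:
            continue
        chosen = rng.choice(mem, size=min(take[i], len(mem)), replace=False)
        train_idx.extend(chosen.tolist())
    train = set(train_idx)
    return HoldoutSplit(
        train_ids=tuple(ids[i] for i in sorted(train)),
        holdout_ids=tuple(ids[i] for i in range(m) if i not in train),
        v=v, g=g)


def holdout_evaluate(solutions, matrix: MutationMatrix,
                     clinical: pd.DataFrame, split: HoldoutSplit,
                     B: int = 100_000, seed=None) -> list:
    """Monte-Carlo log-rank p-values of training solutions on the holdout set.

    The tail matches each solution's training direction (upper for reduced
    survival, lower for increased).  A solution mutating zero holdout
    samples gets p = 1 with a warning.
    """
    hold = list(split.holdout_ids)
    sub = matrix.subset_samples(hold)
    clin = clinical.set_index("sample_id").loc[hold]
    surv = rank_samples(clin["time"].to_numpy(), clin["status"].to_numpy())
    out = []
    rng = np.random.default_rng(seed)
    for sol in solutions:
        rows = sub.rows_for(sol.genes)
        x = surv.to_rank_order((rows.sum(axis=0) > 0).astype(np.uint8))
        if x.sum() == 0:
            warnings.warn(f"solution {sol.genes} mutates no holdout sample; p=1")
            out.append(1.0)
            continue
        tail = "upper" if sol.direction == "reduced" else "lower"
        out.append(montecarlo_pvalue(x, surv, B=B, tail=tail,
                                     seed=rng.integers(2**31 - 1)))
    return out
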