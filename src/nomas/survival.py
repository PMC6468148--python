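"""Log-rank scoring of patient populations defined by gene-set mutations.

The central quantity is the log-rank numerator

    V(x, c) = sum_j c_j * (x_j - (m1 - sum_{i<j} x_i) / (m - j + 1))

evaluated over samples sorted by increasing survival time, where ``x`` marks
membership in the mutated population P1 and ``c`` marks exact (uncensored)
survival times.  V is linear in ``x``:

    V(x) = sum_i x_i * b_i,      b_i = c_i - sum_{j<=i} c_j / (m - j + 1)

which this module precomputes once per cohort (``SurvivalData.event_weights``)
so that scoring a gene set costs O(m) — and scoring the union of two already
scored sets costs only the size of their overlap.  The subnetwork score is
w = V / sqrt(m1*(m-m1)); dividing further by the cohort constant f(c) yields
the normalized statistic, asymptotically N(0,1) under the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SurvivalData",
    "ScoreDecomposition",
    "rank_samples",
    "logrank_V",
    "f_of_c",
    "score_w",
    "gene_set_indicator",
    "montecarlo_pvalue",
]


@dataclass(frozen=True)
class SurvivalData:
    """Rank-ordered survival data for a cohort of ``m`` samples.

    ``order[r]`` gives the original sample position holding survival rank
    ``r`` (rank 0 = shortest survival).  ``c`` and ``raw_times`` are stored
    in rank order.
    """

    m: int
    order: np.ndarray       # int, shape (m,): rank -> original index
    c: np.ndarray           # uint8, rank order; 1 = event/exact, 0 = censored
    raw_times: np.ndarray   # float, rank order (non-decreasing)

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need at least 2 samples")
        if len(self.c) != self.m or len(self.order) != self.m:
            raise ValueError("inconsistent lengths in SurvivalData")
        if sorted(self.order.tolist()) != list(range(self.m)):
            raise ValueError("order is not a permutation of 0..m-1")

    @property
    def event_weights(self) -> np.ndarray:
        """Linear coefficients b with V(x) = x @ b for rank-ordered x."""
        if not hasattr(self, "_b"):
            c = self.c.astype(np.float64)
            a = c / (self.m - np.arange(self.m, dtype=np.float64))
            object.__setattr__(self, "_b", c - np.cumsum(a))
        return self._b

    @property
    def f_c(self) -> float:
        return f_of_c(self)

    def to_rank_order(self, values: np.ndarray) -> np.ndarray:
        """Reorder a vector given in original sample order to rank order."""
        values = np.asarray(values)
        if values.shape[-1] != self.m:
            raise ValueError("length mismatch with cohort size")
        return values[..., self.order]


@dataclass(frozen=True)
class ScoreDecomposition:
    """Factorized log-rank score of one population split."""

    V: float
    sigma_x: float          # sqrt(m1*(m-m1))
    f_c: float              # censoring factor, cohort constant
    w: float                # V / sigma_x  (0 at degenerate splits)
    normalized: float       # w / f_c      (0 if f_c == 0)
    m1: int = 0


def rank_samples(times, censor) -> SurvivalData:
    """Sort samples by increasing survival time into a :class:`SurvivalData`.

    Ties are broken deterministically: events before censored samples, then
    original index; a warning is emitted because tied times violate the
    model's no-ties assumption.
    """
    times = np.asarray(times, dtype=np.float64)
    censor = np.asarray(censor)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != censor.shape:
        raise ValueError("times and censor must have equal length")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    if times.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.isin(censor, (0, 1)).all():
        raise ValueError("censoring status must be 0 or 1")
    m = times.size
    if np.unique(times).size < m:
        warnings.warn("tied survival times; using (time, event-first, index) order")
    # lexsort: last key is primary
    order = np.lexsort((np.arange(m), -censor.astype(int), times))
    return SurvivalData(
        m=m,
        order=order,
        c=censor[order].astype(np.uint8),
        raw_times=times[order],
    )


def _as_rank_x(x, s: SurvivalData) -> np.ndarray:
    x = np.asarray(x)
    if x.shape[-1] != s.m:
        raise ValueError(f"population vector length {x.shape[-1]} != m={s.m}")
    return x.astype(np.float64)


def logrank_V(x, s: SurvivalData) -> float:
    """Log-rank numerator V for a rank-ordered population indicator x."""
    return float(_as_rank_x(x, s) @ s.event_weights)


def f_of_c(s: SurvivalData) -> float:
    """Censoring factor f(c) = sqrt((Σc_j − Σ c_j/(m−j+1)) / (m(m−1)))."""
    m = s.m
    c = s.c.astype(np.float64)
    a = c / (m - np.arange(m, dtype=np.float64))
    val = (c.sum() - a.sum()) / (m * (m - 1))
    return float(np.sqrt(max(val, 0.0)))


def score_w(x, s: SurvivalData) -> ScoreDecomposition:
    """Full score decomposition of the split defined by x (rank order).

    At degenerate splits (m1 in {0, m}) V vanishes identically and w is
    defined as 0: a set mutating every sample or none carries no signal.
    """
    xr = _as_rank_x(x, s)
    m1 = int(round(xr.sum()))
    V = float(xr @ s.event_weights)
    fc = f_of_c(s)
    if m1 == 0 or m1 == s.m:
        return ScoreDecomposition(V=0.0, sigma_x=0.0, f_c=fc, w=0.0,
                                  normalized=0.0, m1=m1)
    sigma_x = float(np.sqrt(m1 * (s.m - m1)))
    w = V / sigma_x
    normalized = w / fc if fc > 0 else 0.0
    return ScoreDecomposition(V=V, sigma_x=sigma_x, f_c=fc, w=w,
                              normalized=normalized, m1=m1)


def gene_set_indicator(matrix, genes, s: SurvivalData) -> np.ndarray:
    """Rank-ordered indicator x^S: x_j = 1 iff >=1 gene of S mutated in j.

    ``matrix`` is a :class:`~nomas.data_io.MutationMatrix` whose sample
    order matches the original order underlying ``s``.
    """
    rows = matrix.rows_for(genes)
    x = (rows.sum(axis=0) > 0).astype(np.uint8)
    return s.to_rank_order(x)


def _sample_fixed_m1(rng, B, m, m1):
    """B random binary vectors of length m with exactly m1 ones."""
    U = rng.random((B, m))
    idx = np.argpartition(U, m1 - 1, axis=1)[:, :m1]
    X = np.zeros((B, m), dtype=np.float64)
    np.put_along_axis(X, idx, 1.0, axis=1)
    return X


def null_statistics(s: SurvivalData, m1: int, B: int, seed=None,
                    chunk: int = 20000) -> np.ndarray:
    """Draw B normalized log-rank statistics under the fixed-m1 null."""
    rng = np.random.default_rng(seed)
    b = s.event_weights
    fc = f_of_c(s)
    denom = np.sqrt(m1 * (s.m - m1)) * fc
    if denom == 0:
        raise ValueError("degenerate null (m1 in {0,m} or no events)")
    out = np.empty(B)
    for lo in range(0, B, chunk):
        hi = min(B, lo + chunk)
        X = _sample_fixed_m1(rng, hi - lo, s.m, m1)
        out[lo:hi] = (X @ b) / denom
    return out


def montecarlo_pvalue(x, s: SurvivalData, B: int = 100_000,
                      tail: str = "two", seed=None) -> float:
    """Monte-Carlo log-rank p-value, conditioning on the observed m1.

    Draws ``B`` uniformly random population labelings with exactly m1
    mutated samples and applies the add-one estimator
    (#{as extreme} + 1) / (B + 1), so the estimate is never exactly 0.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if tail not in ("upper", "lower", "two"):
        raise ValueError(f"unknown tail {tail!r}")
    xr = _as_rank_x(x, s)
    m1 = int(round(xr.sum()))
    if m1 == 0 or m1 == s.m:
        warnings.warn("degenerate population (m1 in {0, m}); p-value = 1")
        return 1.0
    obs = score_w(xr, s).normalized
    draws = null_statistics(s, m1, B, seed=seed)
    # the null is discrete: count exact ties as "at least as extreme",
    # tolerating last-ulp differences between scoring paths
    eps = 1e-9 * max(1.0, abs(obs))
    if tail == "upper":
        hits = int(np.sum(draws >= obs - eps))
    elif tail == "lower":
        hits = int(np.sum(draws <= obs + eps))
    else:
        hits = int(np.sum(np.abs(draws) >= abs(obs) - eps))
    return (hits + 1) / (B + 1)
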