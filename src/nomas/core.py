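"""NoMAS: color-coding search for the max connected k-set log-rank problem.

Given an interaction graph, a binary mutation matrix and censored survival
data, NoMAS looks for connected subnetworks S of exactly ``k`` genes whose
"mutated in >= 1 gene of S" population split maximizes the log-rank score
w(S) = V(x^S) / sqrt(m1 (m - m1)) (association with reduced survival), or
-w(S) (increased survival).

Each iteration colors every vertex uniformly at random with one of ``k``
colors and fills a (2^k - 1) x |V| table whose entry (T, u) stores one
connected *colorful* subnetwork anchored at u with colorset exactly T.
Because w is not set additive, the per-coloring table is a heuristic (the
stored entry maximizes w among candidates built from smaller entries, which
need not contain the colorful optimum); across L independent colorings the
best full-colorset entry is reported.  k!/k^k >= e^-k of colorings make any
fixed k-set colorful, so L = ceil(ln(1/delta) e^k) iterations bound the
probability of never seeing it colorful by delta.
"""

from __future__ import annotations

import math
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import _dp
from .data_io import HarmonizedData, MutationMatrix
from .survival import SurvivalData, f_of_c

__all__ = [
    "Coloring",
    "RunConfig",
    "ScoredSubnetwork",
    "DPTable",
    "Instance",
    "color_graph",
    "init_table",
    "fill_table",
    "parallel_fill",
    "run_nomas",
    "iterations_for",
]

DIRECTIONS = ("reduced", "increased")  # reduced survival: maximize +w


def _sign(direction: str) -> float:
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    return 1.0 if direction == "reduced" else -1.0


def iterations_for(k: int, delta: float) -> int:
    """Iteration count L = ceil(ln(1/delta) * e^k) for failure probability delta."""
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    return max(1, math.ceil(math.log(1.0 / delta) * math.exp(k)))


@dataclass(frozen=True)
class Coloring:
    """A uniform random k-coloring of the instance's vertices."""

    k: int
    colors: np.ndarray  # int64, aligned with Instance.nodes
    seed: object = None

    def color_of(self, instance: "Instance", gene: str) -> int:
        return int(self.colors[instance.node_index[gene]]) + 1


@dataclass
class RunConfig:
    """Parameters of one NoMAS run."""

    k: int
    L: int | None = None          # iterations; derived from delta if None
    delta: float | None = None
    directions: tuple = DIRECTIONS
    seed: int = 0
    threads: int = 1
    top_n: int = 10

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if isinstance(self.directions, str):
            self.directions = (self.directions,)
        for d in self.directions:
            _sign(d)
        if self.L is None:
            self.L = iterations_for(self.k, self.delta) if self.delta else 256
        if self.L < 1:
            raise ValueError("L must be >= 1")


@dataclass(frozen=True)
class ScoredSubnetwork:
    """A connected k-gene set with its log-rank score."""

    genes: tuple
    w: float
    normalized: float
    direction: str
    iteration: int = -1

    @property
    def adjusted(self) -> float:
        """Direction-adjusted score (what the search maximizes)."""
        return _sign(self.direction) * self.w


class Instance:
    """Aligned arrays for fast repeated scoring on one dataset.

    Nodes are the graph's vertices in sorted symbol order, so positional
    tie-breaking equals lexicographic tie-breaking on gene symbols.
    Sample bit j (rank order) lives in word j // 63, bit j % 63.
    """

    def __init__(self, graph: nx.Graph, matrix: MutationMatrix,
                 survival: SurvivalData):
        self.graph = graph
        self.matrix = matrix
        self.survival = survival
        self.nodes = sorted(graph.nodes())
        missing = [g for g in self.nodes if g not in matrix._index]
        if missing:
            raise ValueError(f"graph nodes missing from mutation matrix: {missing[:5]}")
        self.node_index = {g: i for i, g in enumerate(self.nodes)}
        n = len(self.nodes)
        indptr = np.zeros(n + 1, dtype=np.int64)
        nbrs = []
        for i, g in enumerate(self.nodes):
            adj = sorted(self.node_index[h] for h in graph.neighbors(g))
            nbrs.extend(adj)
            indptr[i + 1] = len(nbrs)
        self.indptr = indptr
        self.indices = np.asarray(nbrs, dtype=np.int64)
        rows = matrix.rows_for(self.nodes)
        ranked = rows[:, survival.order]          # columns in rank order
        self.bits = _dp.pack_bits(ranked)
        b = survival.event_weights
        self.row_V = ranked.astype(np.float64) @ b
        self.row_m1 = ranked.sum(axis=1).astype(np.int64)
        nw = self.bits.shape[1]
        self.bpad = np.zeros(nw * _dp.WORD_BITS)
        self.bpad[: survival.m] = b
        self.f_c = f_of_c(survival)

    @classmethod
    def from_harmonized(cls, data: HarmonizedData) -> "Instance":
        return cls(data.graph, data.matrix, data.survival)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return self.survival.m

    def score_set(self, genes) -> tuple:
        """(w, normalized, m1) of a gene set, from the packed rows."""
        idx = [self.node_index[g] if isinstance(g, str) else int(g) for g in genes]
        union = np.bitwise_or.reduce(self.bits[idx], axis=0)
        V = 0.0
        m1 = 0
        for wd, word in enumerate(union):
            word = int(word)
            base = wd * _dp.WORD_BITS
            while word:
                low = word & -word
                V += self.bpad[base + low.bit_length() - 1]
                m1 += 1
                word ^= low
        if m1 == 0 or m1 == self.m:
            return 0.0, 0.0, m1
        w = V / math.sqrt(m1 * (self.m - m1))
        return w, (w / self.f_c if self.f_c > 0 else 0.0), m1


def color_graph(instance: Instance, k: int, seed) -> Coloring:
    """Assign each vertex an i.i.d. uniform color in {1..k} (stored 0-based)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    return Coloring(k=k, colors=rng.integers(0, k, instance.n, dtype=np.int64),
                    seed=seed)


class DPTable:
    """The (2^k - 1) x |V| color-coding table for one coloring/direction."""

    def __init__(self, instance: Instance, coloring: Coloring, direction: str):
        self.instance = instance
        self.coloring = coloring
        self.direction = direction
        self.sign = _sign(direction)
        k, n = coloring.k, instance.n
        nm = 1 << k
        nw = instance.bits.shape[1]
        self.present = np.zeros((nm, n), dtype=np.uint8)
        self.entV = np.zeros((nm, n))
        self.entm1 = np.zeros((nm, n), dtype=np.int64)
        self.entbits = np.zeros((nm, n, nw), dtype=np.int64)
        self.verts = np.full((nm, n, k), -1, dtype=np.int32)
        self.n_candidates = 0
        self.filled = False

    @property
    def k(self) -> int:
        return self.coloring.k

    def entry(self, colorset: int, gene: str):
        """Gene tuple stored at (colorset mask, gene), or None."""
        u = self.instance.node_index[gene]
        if not self.present[colorset, u]:
            return None
        sz = bin(colorset).count("1")
        return tuple(self.instance.nodes[i] for i in self.verts[colorset, u, :sz])

    def full_row_solutions(self, iteration: int = -1):
        """Distinct subnetworks stored in the full-colorset row."""
        inst = self.instance
        full = (1 << self.k) - 1
        seen = {}
        for u in np.flatnonzero(self.present[full]):
            vs = tuple(int(i) for i in self.verts[full, u, : self.k])
            if vs in seen:
                continue
            m1 = int(self.entm1[full, u])
            V = float(self.entV[full, u])
            if m1 == 0 or m1 == inst.m:
                w = 0.0
            else:
                w = V / math.sqrt(m1 * (inst.m - m1))
            norm = w / inst.f_c if inst.f_c > 0 else 0.0
            seen[vs] = ScoredSubnetwork(
                genes=tuple(inst.nodes[i] for i in vs),
                w=w, normalized=norm, direction=self.direction,
                iteration=iteration)
        return list(seen.values())


def init_table(instance: Instance, coloring: Coloring,
               direction: str = "reduced") -> DPTable:
    """Create a table with the singleton rows W({C(u)}, u) = {u} filled."""
    t = DPTable(instance, coloring, direction)
    for u in range(instance.n):
        mask = 1 << int(coloring.colors[u])
        t.present[mask, u] = 1
        t.entV[mask, u] = instance.row_V[u]
        t.entm1[mask, u] = instance.row_m1[u]
        t.entbits[mask, u] = instance.bits[u]
        t.verts[mask, u, 0] = u
    return t


def _masks_by_size(k: int):
    groups = [[] for _ in range(k + 1)]
    for mask in range(1, 1 << k):
        groups[bin(mask).count("1")].append(mask)
    return [np.asarray(g, dtype=np.int64) for g in groups]


def fill_table(table: DPTable, threads: int = 1, kernel=None) -> DPTable:
    """Fill the table in increasing colorset size.

    ``kernel`` is a plug-in point for alternative candidate-merging rules:
    any callable with the signature of :func:`nomas._dp.fill_group` may be
    supplied; the default stores the candidate of maximum direction-adjusted
    score (ties to the lexicographically smallest vertex set).
    """
    if kernel is None:
        kernel = _dp.fill_group
    inst = table.instance
    if threads < 1:
        raise ValueError("threads must be >= 1")
    if threads > inst.n:
        warnings.warn(f"threads={threads} > |V|={inst.n}; clamped")
        threads = inst.n
    groups = _masks_by_size(table.k)
    all_cols = np.arange(inst.n, dtype=np.int64)
    chunks = np.array_split(all_cols, threads)
    counters = [np.zeros(1, dtype=np.int64) for _ in range(threads)]

    def work(ti, masks):
        kernel(masks, chunks[ti], table.coloring.colors,
               inst.indptr, inst.indices,
               table.present, table.entV, table.entm1, table.entbits,
               table.verts, inst.bpad, inst.m, table.sign,
               _dp._POP16, counters[ti])

    for size in range(2, table.k + 1):
        masks = groups[size]
        if threads == 1:
            work(0, masks)
        else:
            # colorset-group barrier: rows of group i read only groups < i,
            # and workers own disjoint columns, so this is race-free
            with ThreadPoolExecutor(max_workers=threads) as pool:
                list(pool.map(lambda ti: work(ti, masks), range(threads)))
    table.n_candidates = int(sum(c[0] for c in counters))
    table.filled = True
    return table


def parallel_fill(table: DPTable, threads: int) -> DPTable:
    """Multi-worker fill; contract: results identical to the serial fill."""
    return fill_table(table, threads=threads)


def run_nomas(graph_or_instance, matrix=None, survival=None,
              config: RunConfig | None = None, **kwargs):
    """Run L color-coding iterations; return top subnetworks per direction.

    Returns a dict mapping direction -> list of :class:`ScoredSubnetwork`
    sorted by decreasing direction-adjusted score, deduplicated across all
    table entries and iterations.  Coloring i is drawn from the substream
    (seed, i), so results for the first L' < L iterations are a prefix of a
    longer run with the same seed.
    """
    if config is None:
        config = RunConfig(**kwargs)
    if isinstance(graph_or_instance, Instance):
        inst = graph_or_instance
    elif isinstance(graph_or_instance, HarmonizedData):
        inst = Instance.from_harmonized(graph_or_instance)
    else:
        inst = Instance(graph_or_instance, matrix, survival)
    if config.k > inst.n:
        raise ValueError(f"k={config.k} exceeds |V|={inst.n}")
    if inst.row_m1.sum() == 0:
        raise ValueError("no mutated genes in the instance")

    best: dict = {d: {} for d in config.directions}
    for i in range(config.L):
        coloring = color_graph(inst, config.k, seed=[config.seed, i])
        for d in config.directions:
            table = fill_table(init_table(inst, coloring, d),
                               threads=config.threads)
            for sol in table.full_row_solutions(iteration=i):
                key = frozenset(sol.genes)
                if key not in best[d]:
                    # re-score from the packed rows: reported scores are
                    # exact, not carried DP arithmetic
                    w, norm, _ = inst.score_set(sol.genes)
                    best[d][key] = ScoredSubnetwork(
                        genes=sol.genes, w=w, normalized=norm,
                        direction=d, iteration=i)
    out = {}
    for d in config.directions:
        ranked = sorted(best[d].values(), key=lambda s: (-s.adjusted, s.genes))
        out[d] = ranked[: config.top_n]
    return out
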