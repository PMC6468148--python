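"""Synthetic instances under the planted subnetwork model.

The generative model plants one connected gene set D of size k whose
mutations are concentrated in the shortest-surviving quarter of the cohort:
for each of the floor(m/4) lowest-survival samples, with probability ``p``
one gene of D chosen uniformly at random is mutated.  On top of that every
gene of D carries passenger mutations at rate 0.01 in every sample, and
every gene outside D mutates i.i.d. at its own background frequency,
independent of survival and censoring.  Censored samples are chosen
uniformly at random at a configurable ratio.

Survival times are the ranks 1..m themselves (the log-rank statistic only
depends on ranks); the sample order in the emitted matrix is randomly
permuted so downstream code cannot rely on columns being pre-sorted.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import MutationMatrix
from .survival import SurvivalData, rank_samples

__all__ = [
    "PlantedModelConfig",
    "SyntheticDataset",
    "random_graph",
    "random_connected_subnetwork",
    "planted_model",
    "null_model",
    "default_background_freqs",
    "check_model_conditions",
]


@dataclass
class PlantedModelConfig:
    """Parameters of the planted subnetwork model.

    ``censor_ratio`` defaults to 0.3, a realistic fraction for an
    aggressive-cancer cohort in which most patients reach the event
    during follow-up.
    """

    k: int = 5
    p: float = 0.85              # planted mutation probability per low-survival sample
    passenger_rate: float = 0.01  # within-D background rate
    background_freqs: object = None  # vector, scalar, or None -> heavy-tailed draw
    censor_ratio: float = 0.3
    m: int = 268
    seed: int = 0

    def __post_init__(self):
        for name in ("p", "passenger_rate", "censor_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.k < 1 or self.m < 4:
            raise ValueError("need k >= 1 and m >= 4")


@dataclass
class SyntheticDataset:
    """A planted-model draw with its ground truth."""

    matrix: MutationMatrix
    clinical: pd.DataFrame
    survival: SurvivalData
    graph: nx.Graph
    planted: tuple                 # the gene set D, sorted
    planted_samples: tuple         # sample IDs that received a planted mutation
    config: PlantedModelConfig


def random_graph(n: int, avg_degree: float = 8.0,
                 model: str = "erdos_renyi", seed=None) -> nx.Graph:
    """Connected random interaction graph over genes g0000..; largest
    component is retained (with a warning via node count reduction)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    nx_seed = int(rng.integers(0, 2**31 - 1))
    if model == "erdos_renyi":
        p = min(1.0, avg_degree / (n - 1))
        g = nx.gnp_random_graph(n, p, seed=nx_seed)
    elif model == "barabasi_albert":
        mm = max(1, int(round(avg_degree / 2)))
        g = nx.barabasi_albert_graph(n, mm, seed=nx_seed)
    elif model == "complete":
        g = nx.complete_graph(n)
    else:
        raise ValueError(f"unknown model {model!r}")
    if not nx.is_connected(g):
        comp = max(nx.connected_components(g), key=len)
        g = g.subgraph(comp).copy()
    width = max(4, len(str(n)))
    mapping = {v: f"g{i:0{width}d}" for i, v in enumerate(sorted(g.nodes()))}
    return nx.relabel_nodes(g, mapping)


def random_connected_subnetwork(graph: nx.Graph, k: int, seed=None) -> tuple:
    """Pick a connected k-set by a simple random walk from a uniform start."""
    nodes = sorted(graph.nodes())
    if k > len(nodes):
        raise ValueError(f"k={k} exceeds |V|={len(nodes)}")
    rng = np.random.default_rng(seed)
    current = nodes[int(rng.integers(len(nodes)))]
    visited = {current}
    guard = 0
    while len(visited) < k:
        nbrs = sorted(graph.neighbors(current))
        if not nbrs:
            raise ValueError("graph is disconnected at the walk's start")
        current = nbrs[int(rng.integers(len(nbrs)))]
        visited.add(current)
        guard += 1
        if guard > 10_000 * k * max(1, len(nodes)):
            raise RuntimeError("random walk failed to collect k vertices")
    return tuple(sorted(visited))


def default_background_freqs(n: int, m: int, rng) -> np.ndarray:
    """Heavy-tailed per-gene mutation frequencies, clipped to [3/m, 0.15].

    Emulates the long-tailed frequency spectrum of passenger mutations in
    exome studies: most genes rare, a few recurrently mutated.
    """
    raw = 0.01 * (1.0 + rng.pareto(1.5, size=n))
    return np.clip(raw, 3.0 / m, 0.15)


def planted_model(graph: nx.Graph, config: PlantedModelConfig) -> SyntheticDataset:
    """Draw one dataset from the planted subnetwork model."""
    nodes = sorted(graph.nodes())
    n, m, k = len(nodes), config.m, config.k
    if k > n:
        raise ValueError(f"k={k} exceeds |V|={n}")
    rng = np.random.default_rng(config.seed)
    D = random_connected_subnetwork(graph, k, seed=rng)
    d_idx = np.asarray([nodes.index(g) for g in D])
    in_d = np.zeros(n, dtype=bool)
    in_d[d_idx] = True

    # per-gene background frequencies for genes outside D
    bf = config.background_freqs
    if bf is None:
        freqs = default_background_freqs(n, m, rng)
    elif np.isscalar(bf):
        freqs = np.full(n, float(bf))
    else:
        freqs = np.asarray(bf, dtype=np.float64)
        if freqs.shape != (n,):
            raise ValueError("background_freqs must have one entry per gene")

    # M_rank: columns ordered by survival rank (0 = shortest survival)
    M_rank = np.zeros((n, m), dtype=np.uint8)
    M_rank[~in_d] = rng.random((n - k, m)) < freqs[~in_d, None]
    M_rank[in_d] = rng.random((k, m)) < config.passenger_rate

    q = m // 4
    hit = rng.random(q) < config.p
    chosen = d_idx[rng.integers(0, k, size=q)]
    planted_cols = np.flatnonzero(hit)
    M_rank[chosen[planted_cols], planted_cols] = 1

    n_cens = int(round(config.censor_ratio * m))
    c_rank = np.ones(m, dtype=np.uint8)
    c_rank[rng.choice(m, size=n_cens, replace=False)] = 0

    # emit samples in a random order; times are the ranks 1..m
    sample_perm = rng.permutation(m)          # column j <- rank sample_perm[j]
    samples = [f"s{j:04d}" for j in range(m)]
    matrix = MutationMatrix(nodes, samples, M_rank[:, sample_perm])
    clinical = pd.DataFrame({
        "sample_id": samples,
        "time": (sample_perm + 1).astype(float),
        "status": c_rank[sample_perm].astype(int),
    })
    survival = rank_samples(clinical["time"].to_numpy(),
                            clinical["status"].to_numpy())
    rank_to_col = np.argsort(sample_perm)
    planted_sample_ids = tuple(samples[rank_to_col[r]] for r in planted_cols)
    return SyntheticDataset(matrix=matrix, clinical=clinical, survival=survival,
                            graph=graph, planted=D,
                            planted_samples=planted_sample_ids, config=config)


def null_model(graph: nx.Graph, m: int, background_rate: float = 0.1,
               censor_ratio: float = 0.3, seed=None) -> SyntheticDataset:
    """Dataset with no planted signal: i.i.d. background mutations only."""
    cfg = PlantedModelConfig(k=1, p=0.0, passenger_rate=background_rate,
                             background_freqs=background_rate,
                             censor_ratio=censor_ratio, m=m, seed=seed)
    ds = planted_model(graph, cfg)
    return SyntheticDataset(matrix=ds.matrix, clinical=ds.clinical,
                            survival=ds.survival, graph=graph,
                            planted=(), planted_samples=(), config=cfg)


def check_model_conditions(dataset: SyntheticDataset, c: float = 0.5,
                           c_prime: float = 0.5) -> dict:
    """Diagnostics for the planted-model conditions on the drawn dataset.

    Evaluates, with V the unnormalized log-rank numerator:
    (i)   V(D) >= c * sqrt(m);
    (ii)  V(D) - V(D \\ {g}) >= c' * sqrt(m) / k for every g in D;
    (iii) V({g}) > 0 for every g in D.
    Condition (iv) — independence of background mutations from survival —
    holds by construction and is not re-tested here.
    """
    ds = dataset
    s = ds.survival
    D = list(ds.planted)
    if not D:
        return {"planted_empty": True}
    from .survival import gene_set_indicator, logrank_V

    def V_of(genes):
        return logrank_V(gene_set_indicator(ds.matrix, genes, s), s)

    m = s.m
    k = len(D)
    VD = V_of(D)
    marginals = {g: VD - V_of([h for h in D if h != g]) for g in D}
    singles = {g: V_of([g]) for g in D}
    return {
        "V_D": VD,
        "cond_i": VD >= c * np.sqrt(m),
        "marginals": marginals,
        "cond_ii": all(v >= c_prime * np.sqrt(m) / k for v in marginals.values()),
        "single_V": singles,
        "cond_iii": all(v > 0 for v in singles.values()),
        "c": c, "c_prime": c_prime,
    }
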