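"""Comparators for the max connected k-set log-rank problem.

* exhaustive enumeration of all connected k-sets (the oracle);
* three greedy seed-and-extend strategies (G1, G2, G3) — reconstructions of
  the neighborhood-growing family of heuristics (seed at every node, extend
  to size k); see docs/methods.md for the exact rules;
* the additive single-gene comparator: score a(S) = sum_g -log10 p(g) with
  genes partitioned by direction of association, optimized by the same
  color-coding DP (the additive score makes each colorful optimum exact
  per coloring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from . import _dp
from .core import Instance, ScoredSubnetwork, _masks_by_size, _sign
from .survival import SurvivalData, score_w

__all__ = [
    "GeneScore",
    "AdditiveSolution",
    "enumerate_connected_subgraphs",
    "exhaustive_search",
    "greedy_grow",
    "greedy_search",
    "single_gene_pvalues",
    "additive_search",
]

_P_FLOOR = 1e-300  # keep 0 < p <= 1 when the normal tail underflows


@dataclass(frozen=True)
class GeneScore:
    """Single-gene log-rank association."""

    gene: str
    pvalue: float        # one-sided, in the gene's own direction
    sign: int            # +1 reduced survival, -1 increased, 0 undefined
    additive: float      # -log10 pvalue


@dataclass(frozen=True)
class AdditiveSolution:
    """Best connected k-set under the additive score a(S)."""

    genes: tuple
    a_score: float
    direction: str
    iteration: int = -1


def enumerate_connected_subgraphs(graph: nx.Graph, k: int):
    """Yield every connected vertex set of size exactly k exactly once.

    Recursive extension with an exclusion rule: subgraphs are only grown
    from vertices ordered after the anchor, and the extension set excludes
    neighbors of the current subgraph, so no set is produced twice.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nodes = sorted(graph.nodes())
    order = {g: i for i, g in enumerate(nodes)}
    adj = {g: set(graph.neighbors(g)) for g in nodes}
    if k > len(nodes):
        return

    def extend(sub, sub_nbrs, ext, anchor_rank):
        if len(sub) == k:
            yield frozenset(sub)
            return
        ext = list(ext)
        while ext:
            w = ext.pop()
            new_ext = ext + [u for u in adj[w]
                             if order[u] > anchor_rank
                             and u not in sub and u not in sub_nbrs]
            yield from extend(sub | {w}, sub_nbrs | adj[w], new_ext,
                              anchor_rank)

    for v in nodes:
        if k == 1:
            yield frozenset((v,))
            continue
        rank = order[v]
        ext0 = [u for u in adj[v] if order[u] > rank]
        yield from extend({v}, adj[v] | {v}, ext0, rank)


def _better(cand_score, cand_genes, best_score, best_genes):
    if best_genes is None or cand_score > best_score:
        return True
    return cand_score == best_score and cand_genes < best_genes


def exhaustive_search(graph: nx.Graph, matrix, survival: SurvivalData,
                      k: int, direction: str = "reduced") -> ScoredSubnetwork:
    """Global optimum of the direction-adjusted score over connected k-sets."""
    inst = graph if isinstance(graph, Instance) else Instance(graph, matrix, survival)
    sign = _sign(direction)
    best_genes, best_score, best_aux = None, -np.inf, None
    for S in enumerate_connected_subgraphs(inst.graph, k):
        genes = tuple(sorted(S))
        w, norm, m1 = inst.score_set(genes)
        adj = sign * w
        if _better(adj, genes, best_score, best_genes):
            best_genes, best_score, best_aux = genes, adj, (w, norm)
    if best_genes is None:
        raise ValueError(f"no connected {k}-set in the graph")
    return ScoredSubnetwork(genes=best_genes, w=best_aux[0],
                            normalized=best_aux[1], direction=direction)


def _grow_greedy(inst: Instance, adj, start, k, variant, sign):
    """Grow one solution from ``start``; returns (genes tuple, adjusted score)
    or None when the component around start is smaller than k."""
    S = [start]
    while len(S) < k:
        in_S = set(S)
        frontier = sorted({v for u in S for v in adj[u]} - in_S)
        if not frontier:
            return None
        best_node, best_pair, best_score = None, None, -np.inf

        if variant in ("G1", "G3"):
            for v in frontier:
                if variant == "G3" and len(S) + 1 < k:
                    # one-step lookahead: judge v by the best (v, v') pair
                    nxt = sorted(({x for u in S + [v] for x in adj[u]}
                                  | set(adj[v])) - in_S - {v})
                    if nxt:
                        sc = max(sign * inst.score_set(S + [v, x])[0]
                                 for x in nxt)
                    else:
                        sc = sign * inst.score_set(S + [v])[0]
                else:
                    sc = sign * inst.score_set(S + [v])[0]
                if _better(sc, (v,), best_score, best_pair):
                    best_node, best_pair, best_score = [v], (v,), sc
        elif variant == "G2":
            for v in frontier:
                sc = sign * inst.score_set(S + [v])[0]
                if _better(sc, (v,), best_score, best_pair):
                    best_node, best_pair, best_score = [v], (v,), sc
            if k - len(S) >= 2:
                # nodes at distance exactly 2, added with their best connector
                dist2 = sorted({w for y in frontier for w in adj[y]}
                               - in_S - set(frontier))
                for w in dist2:
                    for y in sorted(set(adj[w]) & set(frontier)):
                        sc = sign * inst.score_set(S + [y, w])[0]
                        if _better(sc, (y, w), best_score, best_pair):
                            best_node, best_pair, best_score = [y, w], (y, w), sc
        else:
            raise ValueError(f"unknown greedy variant {variant!r}")
        S.extend(best_node)
    genes = tuple(sorted(S))
    return genes, sign * inst.score_set(genes)[0]


def greedy_grow(instance: Instance, start: str, k: int, variant: str = "G1",
                direction: str = "reduced"):
    """Grow one greedy solution from a single start node (None if the start's
    component has fewer than k vertices)."""
    adj = {u: sorted(instance.graph.neighbors(u)) for u in instance.nodes}
    got = _grow_greedy(instance, adj, start, k, variant, _sign(direction))
    if got is None:
        return None
    genes, _ = got
    w, norm, _ = instance.score_set(genes)
    return ScoredSubnetwork(genes=genes, w=w, normalized=norm,
                            direction=direction)


def greedy_search(graph, matrix, survival, k: int, variant: str = "G1",
                  direction: str = "reduced") -> ScoredSubnetwork:
    """Best greedy solution over all start nodes for one variant."""
    if k < 1:
        raise ValueError("k must be >= 1")
    inst = graph if isinstance(graph, Instance) else Instance(graph, matrix, survival)
    sign = _sign(direction)
    adj = {u: sorted(inst.graph.neighbors(u)) for u in inst.nodes}
    best_genes, best_score = None, -np.inf
    for start in inst.nodes:
        got = _grow_greedy(inst, adj, start, k, variant, sign)
        if got is None:
            continue
        genes, sc = got
        if _better(sc, genes, best_score, best_genes):
            best_genes, best_score = genes, sc
    if best_genes is None:
        raise ValueError(f"no start node can grow a connected {k}-set")
    w, norm, _ = inst.score_set(best_genes)
    return ScoredSubnetwork(genes=best_genes, w=w, normalized=norm,
                            direction=direction)


def single_gene_pvalues(matrix, survival: SurvivalData) -> list:
    """Per-gene one-sided asymptotic-normal log-rank p-values."""
    out = []
    for g in matrix.genes:
        x = survival.to_rank_order(matrix.rows_for([g])[0])
        dec = score_w(x, survival)
        if dec.m1 == 0 or dec.m1 == survival.m:
            out.append(GeneScore(gene=g, pvalue=1.0, sign=0, additive=0.0))
            continue
        z = dec.normalized
        p = max(float(stats.norm.sf(abs(z))), _P_FLOOR)
        sgn = 1 if z > 0 else (-1 if z < 0 else 0)
        out.append(GeneScore(gene=g, pvalue=p, sign=sgn,
                             additive=-np.log10(p)))
    return out


def additive_search(graph: nx.Graph, gene_scores, k: int,
                    direction: str = "reduced", L: int = 64, seed: int = 0,
                    top_n: int = 1):
    """Color-coding optimization of a(S) on one direction's gene partition.

    Genes are restricted to those whose single-gene association points in
    ``direction``; the additive objective is exact per coloring whenever the
    optimum is colorful.
    """
    want = 1 if direction == "reduced" else -1
    _sign(direction)
    scores = {gs.gene: gs.additive for gs in gene_scores if gs.sign == want}
    part = [g for g in sorted(graph.nodes()) if g in scores]
    if len(part) < k:
        warnings.warn(f"direction partition has {len(part)} genes < k={k}; "
                      "no solution")
        return []
    sub = graph.subgraph(part)
    nodes = sorted(sub.nodes())
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    indptr = np.zeros(n + 1, dtype=np.int64)
    nbrs = []
    for i, g in enumerate(nodes):
        nbrs.extend(sorted(index[h] for h in sub.neighbors(g)))
        indptr[i + 1] = len(nbrs)
    indices = np.asarray(nbrs, dtype=np.int64)
    node_scores = np.asarray([scores[g] for g in nodes])

    groups = _masks_by_size(k)
    full = (1 << k) - 1
    best: dict = {}
    rng_master = seed
    for it in range(L):
        rng = np.random.default_rng([rng_master, it])
        colors = rng.integers(0, k, n, dtype=np.int64)
        present = np.zeros((1 << k, n), dtype=np.uint8)
        entA = np.zeros((1 << k, n))
        verts = np.full((1 << k, n, k), -1, dtype=np.int32)
        for u in range(n):
            mask = 1 << int(colors[u])
            present[mask, u] = 1
            entA[mask, u] = node_scores[u]
            verts[mask, u, 0] = u
        counter = np.zeros(1, dtype=np.int64)
        cols = np.arange(n, dtype=np.int64)
        for size in range(2, k + 1):
            _dp.fill_group_additive(groups[size], cols, colors, indptr,
                                    indices, present, entA, verts,
                                    _dp._POP16, counter)
        for u in np.flatnonzero(present[full]):
            genes = tuple(nodes[i] for i in verts[full, u, :k])
            key = frozenset(genes)
            if key not in best:
                best[key] = AdditiveSolution(genes=genes,
                                             a_score=float(entA[full, u]),
                                             direction=direction, iteration=it)
    ranked = sorted(best.values(), key=lambda s: (-s.a_score, s.genes))
    return ranked[:top_n]
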