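"""Readers, writers and harmonization for the three standard inputs.

Formats (all plain TSV):

* mutation matrix — gene rows x sample columns, cells 0/1, header row of
  sample IDs, first column ``gene``;
* MAF-lite — two columns ``gene``, ``sample``, one row per mutation record
  (duplicates collapse to a single 1);
* edge list — two gene-symbol columns, ``#`` comments allowed;
* clinical — columns ``sample_id``, ``time``, ``status`` (1 = event).

Gene symbols are matched case-sensitively after whitespace strip; no alias
resolution is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .survival import SurvivalData, rank_samples

__all__ = [
    "MutationMatrix",
    "read_mutation_matrix",
    "read_maf_lite",
    "write_mutation_matrix",
    "read_edge_list",
    "write_edge_list",
    "read_clinical",
    "filter_min_mutated",
    "harmonize",
    "HarmonizedData",
]


@dataclass
class MutationMatrix:
    """Binary gene x sample somatic mutation matrix."""

    genes: list
    samples: list
    M: np.ndarray  # uint8, shape (n_genes, n_samples)
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=np.uint8)
        if self.M.shape != (len(self.genes), len(self.samples)):
            raise ValueError("matrix shape does not match gene/sample labels")
        if not np.isin(self.M, (0, 1)).all():
            raise ValueError("mutation matrix entries must be 0/1")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def m(self) -> int:
        return len(self.samples)

    def rows_for(self, genes) -> np.ndarray:
        try:
            idx = [self._index[g] for g in genes]
        except KeyError as e:
            raise KeyError(f"unknown gene {e.args[0]!r}") from None
        return self.M[idx]

    def subset_samples(self, sample_ids) -> "MutationMatrix":
        pos = {s: j for j, s in enumerate(self.samples)}
        cols = [pos[s] for s in sample_ids]
        return MutationMatrix(list(self.genes), list(sample_ids), self.M[:, cols])


def read_mutation_matrix(path) -> MutationMatrix:
    """Read a gene x sample binary TSV (first column ``gene``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
    genes = [g.strip() for g in df["gene"]]
    if len(set(genes)) != len(genes):
        raise ValueError(f"{path}: duplicate gene rows")
    samples = [s.strip() for s in df.columns[1:]]
    body = df.iloc[:, 1:].to_numpy()
    cells = np.char.strip(body.astype(str))
    if not np.isin(cells, ("0", "1")).all():
        bad = cells[~np.isin(cells, ("0", "1"))][0]
        raise ValueError(f"{path}: non-binary cell {bad!r}")
    return MutationMatrix(genes, samples, cells.astype(np.uint8))


def read_maf_lite(path) -> MutationMatrix:
    """Read a two-column (gene, sample) mutation record file and binarize."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "sample"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    genes = sorted({g.strip() for g in df["gene"]})
    samples = sorted({s.strip() for s in df["sample"]})
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: j for j, s in enumerate(samples)}
    M = np.zeros((len(genes), len(samples)), dtype=np.uint8)
    for g, s in zip(df["gene"], df["sample"]):
        M[gi[g.strip()], si[s.strip()]] = 1  # duplicates collapse
    return MutationMatrix(genes, samples, M)


def write_mutation_matrix(matrix: MutationMatrix, path) -> None:
    df = pd.DataFrame(matrix.M, columns=matrix.samples)
    df.insert(0, "gene", matrix.genes)
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> nx.Graph:
    """Read an undirected simple graph from a two-column TSV edge list."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: malformed edge line {line!r}")
            u, v = parts[0].strip(), parts[1].strip()
            if u == v:
                warnings.warn(f"{path}:{lineno}: self-loop {u!r} dropped")
                continue
            g.add_edge(u, v)
    return g


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u}\t{v}\n")


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical TSV (sample_id, time, status); strict parse."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "status"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing clinical column {col!r}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    df["time"] = df["time"].astype(float)
    df["status"] = df["status"].astype(int)
    if not df["status"].isin((0, 1)).all():
        raise ValueError(f"{path}: status must be 0 (censored) or 1 (event)")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs")
    return df


def filter_min_mutated(matrix: MutationMatrix, min_samples: int = 3,
                       drop: bool = False) -> MutationMatrix:
    """Remove mutations in genes mutated in fewer than ``min_samples`` samples.

    By default the affected rows are zeroed but the genes are retained —
    an all-zero gene cannot change any population split, while keeping the
    node preserves its role as a network connector.  ``drop=True`` deletes
    the rows entirely (strict mode).
    """
    if min_samples < 0:
        raise ValueError("min_samples must be >= 0")
    counts = matrix.M.sum(axis=1)
    low = counts < min_samples
    n_low = int(low.sum())
    if n_low:
        warnings.warn(f"{n_low} genes mutated in < {min_samples} samples "
                      f"{'dropped' if drop else 'zeroed'}")
    if drop:
        keep = ~low
        return MutationMatrix([g for g, k in zip(matrix.genes, keep) if k],
                              list(matrix.samples), matrix.M[keep])
    M = matrix.M.copy()
    M[low] = 0
    return MutationMatrix(list(matrix.genes), list(matrix.samples), M)


@dataclass
class HarmonizedData:
    """Aligned mutation matrix, interaction graph and survival data.

    ``matrix`` rows follow ``genes`` (the graph's nodes, sorted); columns
    follow ``matrix.samples``; ``survival.order`` indexes those columns.
    """

    matrix: MutationMatrix
    graph: nx.Graph
    survival: SurvivalData
    report: dict


def harmonize(matrix: MutationMatrix, graph: nx.Graph,
              clinical: pd.DataFrame) -> HarmonizedData:
    """Restrict to shared samples, align genes to the graph's node set.

    Genes present in the matrix but absent from the graph are dropped (with
    a warning); graph nodes without mutation data receive all-zero rows and
    act purely as connectors.  Gene order is the sorted node order, so that
    positional and lexicographic tie-breaking coincide downstream.
    """
    clin_ids = list(clinical["sample_id"])
    shared = [s for s in matrix.samples if s in set(clin_ids)]
    if not shared:
        raise ValueError("no samples shared between mutation matrix and clinical table")
    sub = matrix.subset_samples(shared)

    nodes = sorted(graph.nodes())
    node_set = set(nodes)
    dropped = [g for g in sub.genes if g not in node_set]
    if dropped:
        warnings.warn(f"{len(dropped)} matrix genes absent from the network dropped")
    gi = {g: i for i, g in enumerate(sub.genes)}
    M = np.zeros((len(nodes), len(shared)), dtype=np.uint8)
    for r, g in enumerate(nodes):
        if g in gi:
            M[r] = sub.M[gi[g]]
    aligned = MutationMatrix(nodes, shared, M)

    clin = clinical.set_index("sample_id").loc[shared]
    survival = rank_samples(clin["time"].to_numpy(), clin["status"].to_numpy())

    report = {
        "n_samples": len(shared),
        "n_samples_matrix_only": matrix.m - len(shared),
        "n_samples_clinical_only": len(clin_ids) - len(shared),
        "n_genes_network": len(nodes),
        "n_genes_matrix_dropped": len(dropped),
        "n_genes_zero_rows": int((M.sum(axis=1) == 0).sum()),
        "n_events": int(survival.c.sum()),
    }
    return HarmonizedData(matrix=aligned, graph=graph, survival=survival,
                          report=report)
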