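"""Pairwise Pearson correlation, mutual rank, and signed co-expression networks.

The mutual rank (MR) of a gene pair combines the reciprocal ranks each
gene holds in the other's correlation-sorted partner list; by default the
two ranks are combined by their geometric mean, so MR(A,B) = 1 means A and
B are each other's closest co-expression partner.  Edges are retained when
the pair is both strongly correlated (PCC threshold) and mutually
top-ranked (MR threshold), which suppresses hub-driven spurious links that
a correlation cutoff alone lets through.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .io import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "MutualRankMatrix",
    "CoexpressionNetwork",
    "QCResult",
    "NetworkComparison",
    "PRESETS",
    "qc_filter_samples",
    "compute_pcc",
    "compute_mutual_rank",
    "build_network",
    "compare_networks",
    "write_edge_list",
    "read_edge_list",
]

#: Published threshold presets: the global network uses PCC >= 0.8 and
#: MR <= 55; the conditional (tissue-preferential) network uses MR <= 50.
#: Negative edges use the (-1, -0.3) correlation interval in both.
PRESETS: dict[str, dict[str, float]] = {
    "global": {"pcc_min_pos": 0.8, "pcc_max_neg": -0.3, "mr_max": 55.0},
    "conditional": {"pcc_min_pos": 0.8, "pcc_max_neg": -0.3, "mr_max": 50.0},
}


def _transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log2p1":
        return np.log2(values + 1.0)
    if transform == "none":
        return np.asarray(values, dtype=float)
    raise ValueError(f"unknown transform {transform!r}; use 'log2p1' or 'none'")


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise Pearson correlations, diagonal 1."""

    gene_ids: list[str]
    values: np.ndarray
    dropped_zero_variance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("correlation matrix shape does not match gene ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if np.abs(v).max(initial=0.0) > 1 + 1e-9:
            raise ValueError("correlation values outside [-1, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


@dataclass
class MutualRankMatrix:
    """Symmetric mutual-rank matrix; off-diagonal entries >= 1, diagonal 0."""

    gene_ids: list[str]
    values: np.ndarray
    mode: str = "geometric_mean"
    tail: str = "positive"

    def __post_init__(self) -> None:
        if self.mode not in ("geometric_mean", "product"):
            raise ValueError(f"unknown MR mode {self.mode!r}")
        v = self.values
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("mutual rank matrix is not symmetric")
        off = v[~np.eye(len(v), dtype=bool)]
        if off.size and off.min() < 1:
            raise ValueError("off-diagonal mutual ranks must be >= 1")


@dataclass
class CoexpressionNetwork:
    """Signed co-expression network with PCC and MR edge attributes."""

    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self, sign: str | None = None):
        """Yield (gene_a, gene_b, attrs) with gene_a < gene_b."""
        for u, v, attrs in self.graph.edges(data=True):
            if sign is not None and attrs["sign"] != sign:
                continue
            a, b = sorted((u, v))
            yield a, b, attrs

    def edge_set(self, sign: str | None = None) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.edges(sign)}


@dataclass
class QCResult:
    kept: list[str]
    flagged: list[str]
    sample_correlation: pd.DataFrame
    dendrogram_order: list[str]


def qc_filter_samples(
    matrix: ExpressionMatrix,
    min_mean_corr: float = 0.5,
    linkage: str = "average",
    transform: str = "log2p1",
) -> QCResult:
    """Flag outlier samples by inter-sample correlation and cluster analysis.

    A sample is flagged when its mean Pearson correlation with all other
    samples falls below ``min_mean_corr``.  The hierarchical-clustering
    leaf order of the sample correlation matrix is reported so outliers
    can also be inspected visually, mirroring the usual heatmap-based QC.
    """
    if matrix.n_samples < 3:
        raise ValueError(f"need >= 3 samples for QC, got {matrix.n_samples}")
    x = _transform(matrix.values, transform)
    corr = np.corrcoef(x.T)
    # constant samples yield NaN correlations; treat them as 0 (uninformative)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    samples = matrix.sample_ids
    n = len(samples)
    mean_corr = (corr.sum(axis=1) - 1.0) / (n - 1)
    flagged = [s for s, m in zip(samples, mean_corr) if m < min_mean_corr]
    kept = [s for s in samples if s not in set(flagged)]
    dist = ssd.squareform(np.clip(1.0 - corr, 0.0, None), checks=False)
    order = sch.leaves_list(sch.linkage(dist, method=linkage))
    return QCResult(
        kept=kept,
        flagged=flagged,
        sample_correlation=pd.DataFrame(corr, index=samples, columns=samples),
        dendrogram_order=[samples[i] for i in order],
    )


def compute_pcc(matrix: ExpressionMatrix, transform: str = "log2p1") -> CorrelationMatrix:
    """All-pairs Pearson correlation of gene expression profiles.

    Genes with zero variance under the chosen transform have no defined
    correlation; they are excluded from the matrix and listed in
    ``dropped_zero_variance``.
    """
    if matrix.n_samples < 3:
        raise ValueError(f"need >= 3 samples, got {matrix.n_samples}")
    x = _transform(matrix.values, transform)
    variances = x.var(axis=1)
    keep = variances > 0
    dropped = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    if not keep.any():
        raise ValueError("all genes have zero variance; no correlations defined")
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    corr = np.corrcoef(x[keep])
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(genes, corr, dropped_zero_variance=dropped)


def _rank_matrix(corr: CorrelationMatrix, tail: str) -> np.ndarray:
    """R[i, j] = 1-based rank of gene j among gene i's partners.

    tail="positive" ranks partners by descending PCC (rank 1 = strongest
    positive partner); tail="negative" by ascending PCC.  Ties are broken
    by lexicographic gene id for platform-independent determinism.
    """
    if tail not in ("positive", "negative"):
        raise ValueError(f"unknown tail {tail!r}")
    n = corr.n_genes
    key = -corr.values if tail == "positive" else corr.values.copy()
    np.fill_diagonal(key, -np.inf)  # self first, then shifted out of ranks
    id_order = np.argsort(np.argsort(np.asarray(corr.gene_ids, dtype=object)))
    ranks = np.empty((n, n), dtype=float)
    for i in range(n):
        order = np.lexsort((id_order, key[i]))  # primary: key, secondary: gene id
        ranks[i, order] = np.arange(n)  # 0 = self, 1.. = partners
    return ranks


def compute_mutual_rank(
    corr: CorrelationMatrix,
    tail: str = "positive",
    mode: str = "geometric_mean",
) -> MutualRankMatrix:
    """Mutual rank of every gene pair from the correlation matrix.

    MR(A,B) combines Rank(A->B) and Rank(B->A) by geometric mean
    (default) or plain product.  The diagonal is set to 0 (self pairs are
    never scored).
    """
    if corr.n_genes < 3:
        raise ValueError(f"need >= 3 genes for mutual ranks, got {corr.n_genes}")
    ranks = _rank_matrix(corr, tail)
    prod = ranks * ranks.T
    if mode == "geometric_mean":
        mr = np.sqrt(prod)
    elif mode == "product":
        mr = prod
    else:
        raise ValueError(f"unknown MR mode {mode!r}")
    np.fill_diagonal(mr, 0.0)
    return MutualRankMatrix(list(corr.gene_ids), mr, mode=mode, tail=tail)


def build_network(
    corr: CorrelationMatrix,
    mr_pos: MutualRankMatrix,
    mr_neg: MutualRankMatrix | None = None,
    pcc_min_pos: float = 0.8,
    pcc_max_neg: float = -0.3,
    mr_max: float = 55.0,
) -> CoexpressionNetwork:
    """Construct the signed co-expression network from thresholded PCC + MR.

    A positive edge requires pcc >= pcc_min_pos and positive-tail
    MR <= mr_max; a negative edge requires pcc <= pcc_max_neg and
    negative-tail MR <= mr_max.  All genes appear as nodes, so untouched
    genes remain as isolated nodes.
    """
    genes = list(corr.gene_ids)
    if mr_pos.gene_ids != genes or (mr_neg is not None and mr_neg.gene_ids != genes):
        raise ValueError("correlation and mutual-rank matrices have different gene ids")
    g = nx.Graph()
    g.add_nodes_from(genes)
    n = len(genes)
    iu = np.triu_indices(n, k=1)
    pcc = corr.values[iu]

    def _add(mask: np.ndarray, mr_values: np.ndarray, sign: str) -> None:
        for idx in np.flatnonzero(mask):
            i, j = iu[0][idx], iu[1][idx]
            g.add_edge(
                genes[i], genes[j],
                pcc=float(corr.values[i, j]), mr=float(mr_values[idx]), sign=sign,
            )

    _add((pcc >= pcc_min_pos) & (mr_pos.values[iu] <= mr_max), mr_pos.values[iu], "positive")
    if mr_neg is not None:
        _add((pcc <= pcc_max_neg) & (mr_neg.values[iu] <= mr_max), mr_neg.values[iu], "negative")
    return CoexpressionNetwork(
        graph=g,
        provenance={
            "pcc_min_pos": pcc_min_pos,
            "pcc_max_neg": pcc_max_neg,
            "mr_max": mr_max,
            "mr_mode": mr_pos.mode,
        },
    )


@dataclass
class NetworkComparison:
    jaccard: float
    shared_edges: set[tuple[str, str]]
    n_edges_a: int
    n_edges_b: int
    neighbor_overlap: pd.DataFrame  # per-gene: degree_a, degree_b, shared, jaccard


def compare_networks(a: CoexpressionNetwork, b: CoexpressionNetwork) -> NetworkComparison:
    """Edge-level and per-gene neighborhood agreement between two networks."""
    ea, eb = a.edge_set(), b.edge_set()
    union = ea | eb
    shared = ea & eb
    rows = []
    for gene in sorted(set(a.graph.nodes) | set(b.graph.nodes)):
        na = set(a.graph.neighbors(gene)) if gene in a.graph else set()
        nb = set(b.graph.neighbors(gene)) if gene in b.graph else set()
        u = na | nb
        rows.append({
            "gene": gene,
            "degree_a": len(na),
            "degree_b": len(nb),
            "shared": len(na & nb),
            "jaccard": len(na & nb) / len(u) if u else np.nan,
        })
    return NetworkComparison(
        jaccard=len(shared) / len(union) if union else 1.0,
        shared_edges=shared,
        n_edges_a=len(ea),
        n_edges_b=len(eb),
        neighbor_overlap=pd.DataFrame(rows).set_index("gene"),
    )


def write_edge_list(network: CoexpressionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tpcc\tmr\tsign\n")
        for a, b, attrs in sorted(network.edges()):
            fh.write(f"{a}\t{b}\t{attrs['pcc']:.6f}\t{attrs['mr']:.2f}\t{attrs['sign']}\n")


def read_edge_list(path: str | Path) -> CoexpressionNetwork:
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_a", "gene_b"]:
            raise ValueError("edge list must start with gene_a/gene_b columns")
        for line in fh:
            if not line.strip():
                continue
            a, b, pcc, mr, sign = line.rstrip("\n").split("\t")[:5]
            g.add_edge(a, b, pcc=float(pcc), mr=float(mr), sign=sign)
    return CoexpressionNetwork(graph=g, provenance={"source": str(path)})
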