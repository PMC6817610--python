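"""AUROC evaluation of candidate (PCC, MR) thresholds against GO priors.

Gene pairs co-annotated to a functional term of modest size are treated
as true co-functional pairs; pairs sharing no such term form the negative
class.  Each candidate threshold pair defines a binary classifier (edge /
no edge) whose AUROC against these labels measures how well the
thresholded network concentrates on functionally related genes, and the
best grid cell supplies the published-style cutoffs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .coexpression import CorrelationMatrix, MutualRankMatrix
from .io import GeneSetCollection

__all__ = [
    "LabeledPairSet",
    "label_pairs_from_go",
    "auroc",
    "select_thresholds",
]

Pair = tuple[str, str]


@dataclass
class LabeledPairSet:
    """Unordered gene pairs labeled positive (co-annotated) or negative."""

    positives: list[Pair]
    negatives: list[Pair]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positives = [tuple(sorted(p)) for p in self.positives]
        self.negatives = [tuple(sorted(p)) for p in self.negatives]
        seen = set(self.positives)
        if len(seen) != len(self.positives):
            raise ValueError("duplicate positive pairs")
        dup = seen.intersection(self.negatives)
        if dup or len(set(self.negatives)) != len(self.negatives):
            raise ValueError("duplicate or conflicting negative pairs")

    @property
    def pairs(self) -> list[Pair]:
        return self.positives + self.negatives

    @property
    def labels(self) -> np.ndarray:
        return np.r_[np.ones(len(self.positives)), np.zeros(len(self.negatives))]


def label_pairs_from_go(
    sets: GeneSetCollection,
    genes_in_matrix: list[str],
    size_min: int = 4,
    size_max: int = 20,
    n_negative: int | None = None,
    seed: int = 0,
) -> LabeledPairSet:
    """Build prior-knowledge pair labels from terms of size in [size_min, size_max].

    Term sizes are computed after restriction to the genes present in the
    expression matrix (unmeasured genes cannot contribute pairs).
    Negatives are a seeded uniform sample of pairs sharing no kept term;
    by default as many negatives as positives are drawn.
    """
    if not len(sets):
        raise ValueError("empty gene-set collection")
    measured = set(genes_in_matrix)
    kept_terms = {}
    for gs in sets:
        members = sorted(gs.genes & measured)
        if size_min <= len(members) <= size_max:
            kept_terms[gs.term_id] = members
    if not kept_terms:
        raise ValueError(
            f"no prior-knowledge terms with size in [{size_min}, {size_max}] "
            "after restriction to measured genes"
        )
    positives: set[Pair] = set()
    for members in kept_terms.values():
        positives.update(itertools.combinations(members, 2))

    genes = sorted(measured)
    n = len(genes)
    total_pairs = n * (n - 1) // 2
    n_candidates = total_pairs - len(positives)
    if n_negative is None:
        n_negative = len(positives)
    if n_negative > n_candidates:
        raise ValueError(
            f"requested {n_negative} negatives but only {n_candidates} "
            "non-co-annotated pairs exist"
        )
    rng = np.random.default_rng(seed)
    negatives: set[Pair] = set()
    # rejection sampling; falls back to exhaustive enumeration if the
    # candidate space is nearly saturated
    max_attempts = 50 * max(n_negative, 1)
    attempts = 0
    while len(negatives) < n_negative and attempts < max_attempts:
        i, j = rng.integers(0, n, size=2)
        attempts += 1
        if i == j:
            continue
        pair = (genes[min(i, j)], genes[max(i, j)])
        if pair not in positives:
            negatives.add(pair)
    if len(negatives) < n_negative:
        pool = [
            p for p in itertools.combinations(genes, 2)
            if p not in positives and p not in negatives
        ]
        extra = rng.choice(len(pool), size=n_negative - len(negatives), replace=False)
        negatives.update(pool[k] for k in extra)
    return LabeledPairSet(
        positives=sorted(positives),
        negatives=sorted(negatives),
        provenance={
            "size_min": size_min, "size_max": size_max,
            "n_terms": len(kept_terms), "seed": seed,
        },
    )


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank formulation.

    Equals P(score_pos > score_neg) + 0.5 * P(tie) over all
    positive x negative pairs; ties receive average ranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both positive and negative pairs")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def select_thresholds(
    corr: CorrelationMatrix,
    mr: MutualRankMatrix,
    labeled: LabeledPairSet,
    pcc_grid: list[float],
    mr_grid: list[float],
) -> tuple[pd.DataFrame, pd.Series]:
    """AUROC of every (PCC cut, MR cut) grid cell; returns (table, argmax row).

    Each cell scores a labeled pair 1 when the pair passes the cell's
    filter (pcc >= cut and MR <= cut) and 0 otherwise; the AUROC of this
    binary classifier against the labels measures that cell's network.
    Cells that pass no labeled pair are recorded with NaN AUROC and
    excluded from the argmax; AUROC ties resolve toward the sparser
    network (fewer edges), then the stricter cuts.
    """
    if not len(pcc_grid) or not len(mr_grid):
        raise ValueError("threshold grids must be nonempty")
    if mr.gene_ids != corr.gene_ids:
        raise ValueError("correlation and MR matrices have different gene ids")
    index = {g: i for i, g in enumerate(corr.gene_ids)}
    pairs = labeled.pairs
    missing = [p for p in pairs if p[0] not in index or p[1] not in index]
    if missing:
        raise ValueError(f"labeled pairs involve unmeasured genes, e.g. {missing[0]}")
    ii = np.array([index[a] for a, _ in pairs])
    jj = np.array([index[b] for _, b in pairs])
    pair_pcc = corr.values[ii, jj]
    pair_mr = mr.values[ii, jj]
    labels = labeled.labels

    n = corr.n_genes
    iu = np.triu_indices(n, k=1)
    all_pcc = corr.values[iu]
    all_mr = mr.values[iu]

    rows = []
    for pcc_cut in pcc_grid:
        for mr_cut in mr_grid:
            passed = (pair_pcc >= pcc_cut) & (pair_mr <= mr_cut)
            n_edges = int(((all_pcc >= pcc_cut) & (all_mr <= mr_cut)).sum())
            value = auroc(passed.astype(float), labels) if passed.any() else np.nan
            rows.append({
                "pcc_cut": pcc_cut, "mr_cut": mr_cut,
                "auroc": value, "n_edges": n_edges,
            })
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["auroc"])
    if valid.empty:
        raise ValueError("every grid cell empties the network; argmax undefined")
    best = valid.sort_values(
        by=["auroc", "n_edges", "pcc_cut", "mr_cut"],
        ascending=[False, True, False, True],
        kind="mergesort",
    ).iloc[0]
    return table, best
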