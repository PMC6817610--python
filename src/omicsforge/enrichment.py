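"""Gene-set enrichment by the hypergeometric (one-sided Fisher) test with BH FDR.

Used to annotate co-expression modules and network neighborhoods:
for a query of n genes drawn from a universe of N, a term with K members
in the universe and k members in the query is scored by the upper-tail
probability P(X >= k) of the hypergeometric distribution, then
Benjamini-Hochberg adjusted across the tested terms.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = ["fisher_enrich", "bh_fdr", "hypergeom_upper_tail"]


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n); k = 0 returns 1 by convention."""
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"impossible overlap k={k} for N={N}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Term-by-term enrichment of a gene list against a background universe.

    Returns one row per term with columns term_id, name, k_overlap,
    n_query, K_term, N_universe, p_value, fdr, significant — sorted by
    p-value.  Terms are tested (and counted toward the BH family) only
    when they overlap the query and have >= 2 members in the universe;
    zero-overlap terms are reported with p = 1 and no FDR.  Query genes
    outside the universe are dropped (reported via the ``dropped``
    DataFrame attribute).
    """
    universe_set = set(map(str, universe))
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(map(str, query))
    dropped = sorted(query_set - universe_set)
    query_set &= universe_set
    if not query_set:
        raise ValueError("query is empty after intersection with the universe")
    N, n = len(universe_set), len(query_set)

    rows = []
    for gs in sets:
        members = gs.genes & universe_set
        K = len(members)
        k = len(members & query_set)
        tested = k >= 1 and K >= 2
        rows.append({
            "term_id": gs.term_id, "name": gs.name,
            "k_overlap": k, "n_query": n, "K_term": K, "N_universe": N,
            "p_value": hypergeom_upper_tail(k, N, K, n) if tested else 1.0,
            "tested": tested,
        })
    df = pd.DataFrame(rows)
    df["fdr"] = np.nan
    if df["tested"].any():
        df.loc[df["tested"], "fdr"] = bh_fdr(df.loc[df["tested"], "p_value"])
    df["significant"] = df["fdr"] <= fdr_cut
    df = df.drop(columns="tested").sort_values(
        ["p_value", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
    df.attrs["dropped"] = dropped
    return df
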