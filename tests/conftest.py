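"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from omicsforge.io import ExpressionMatrix


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    """4 genes x 4 samples with hand-checkable correlation structure."""
    data = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 1.0, 4.0],
            "s2": [2.0, 4.0, 3.0, 3.0],
            "s3": [3.0, 6.0, 2.0, 2.0],
            "s4": [4.0, 8.0, 4.0, 1.0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    return ExpressionMatrix(data)


# ---------------------------------------------------------------------------
# Independent oracles (never import the code paths they check)
# ---------------------------------------------------------------------------

def auroc_pair_counting(scores: np.ndarray, labels: np.ndarray) -> float:
    """O(n_pos * n_neg) concordant-pair count: P(s+ > s-) + 0.5 P(tie)."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def kclique_communities_bruteforce(g: nx.Graph, k: int) -> set[frozenset]:
    """Enumerate every k-clique directly and percolate on k-1 sharing."""
    kcliques = [
        frozenset(c)
        for c in (set(q) for q in nx.enumerate_all_cliques(g))
        if len(c) == k
    ]
    parent = list(range(len(kcliques)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(kcliques)), 2):
        if len(kcliques[i] & kcliques[j]) == k - 1:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    comms: dict[int, set] = {}
    for i, c in enumerate(kcliques):
        comms.setdefault(find(i), set()).update(c)
    return {frozenset(c) for c in comms.values()}


def hypergeom_tail_exact(k: int, N: int, K: int, n: int) -> float:
    """Upper tail P(X >= k) by explicit summation of binomial coefficients."""
    if k == 0:
        return 1.0
    denom = math.comb(N, n)
    total = sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
        if n - x <= N - K
    )
    return total / denom


def poisson_tail_exact(c: int, lam: float) -> float:
    """P(X >= c) for Poisson(lam) by direct series summation."""
    below = sum(math.exp(-lam) * lam**x / math.factorial(x) for x in range(c))
    return 1.0 - below


def hmm_posteriors_bruteforce(x, pi, T, E):
    """Posteriors and log-likelihood by summing over every state path."""
    Tlen = x.shape[0]
    S = len(pi)
    post = np.zeros((Tlen, S))
    total = 0.0
    for path in itertools.product(range(S), repeat=Tlen):
        p = pi[path[0]]
        for t in range(1, Tlen):
            p *= T[path[t - 1], path[t]]
        for t in range(Tlen):
            for m in range(x.shape[1]):
                e = E[path[t], m]
                p *= e if x[t, m] else (1 - e)
        total += p
        for t in range(Tlen):
            post[t, path[t]] += p
    return post / total, math.log(total)


def mutual_rank_bruteforce(gene_ids, corr, mode="geometric_mean", tail="positive"):
    """MR by explicit per-gene partner sorting with lexicographic tie-break."""
    n = len(gene_ids)
    rank = np.zeros((n, n))
    for i in range(n):
        partners = [j for j in range(n) if j != i]
        reverse = tail == "positive"
        partners.sort(key=lambda j: ((-corr[i, j]) if reverse else corr[i, j], gene_ids[j]))
        for pos, j in enumerate(partners, start=1):
            rank[i, j] = pos
    mr = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                prod = rank[i, j] * rank[j, i]
                mr[i, j] = math.sqrt(prod) if mode == "geometric_mean" else prod
    return mr


def random_correlation_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """A valid correlation matrix from random data (so PCC semantics hold)."""
    x = rng.standard_normal((n, n + 5))
    c = np.corrcoef(x)
    np.fill_diagonal(c, 1.0)
    return np.clip((c + c.T) / 2, -1, 1)
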