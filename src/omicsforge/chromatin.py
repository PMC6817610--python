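"""Chromatin-state segmentation of binarized epigenomic marks.

The model is a hidden Markov chain over fixed 200-bp genome bins with
multivariate Bernoulli emissions: state s shows mark m as "present" with
probability E[s, m], independently across marks given the state, so the
per-bin emission likelihood is

    P(x | s) = prod_m E[s, m]^x_m * (1 - E[s, m])^(1 - x_m).

Marks are binarized beforehand against a genome-wide Poisson background,
the chain is trained by Baum-Welch EM (scaled forward-backward, random
restarts), bins are assigned their maximum-posterior state, and learned
states are interpreted through emission similarity to a reference model
and fold enrichment over genomic feature classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import poisson

from .io import FeatureAnnotation, SignalTrack, n_bins

__all__ = [
    "BinarizedMarks",
    "ChromatinModel",
    "Segmentation",
    "FoldEnrichmentTable",
    "poisson_cutoff",
    "binarize",
    "learn_model",
    "segment",
    "posterior_marginals",
    "sequence_loglik",
    "compare_models",
    "overlap_enrichment",
    "recommend_n_states",
    "match_states",
]

_PARAM_FLOOR = 1e-6


@dataclass
class BinarizedMarks:
    """Per-bin presence/absence calls for an ordered set of chromatin marks."""

    marks: list[str]
    calls: dict[str, np.ndarray]  # chrom -> (bins x marks) 0/1 matrix
    bin_size: int
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, mat in self.calls.items():
            if mat.ndim != 2 or mat.shape[1] != len(self.marks):
                raise ValueError(f"{chrom!r}: call matrix shape {mat.shape} "
                                 f"does not match {len(self.marks)} marks")
            if not np.isin(mat, (0, 1)).all():
                raise ValueError(f"{chrom!r}: calls must be binary")
            expected = n_bins(self.chrom_sizes[chrom], self.bin_size)
            if mat.shape[0] != expected:
                raise ValueError(f"{chrom!r}: {mat.shape[0]} bins, expected {expected}")

    @property
    def total_bins(self) -> int:
        return sum(m.shape[0] for m in self.calls.values())

    def stacked(self) -> np.ndarray:
        return np.vstack([self.calls[c] for c in sorted(self.calls)])


@dataclass
class ChromatinModel:
    """Multivariate-Bernoulli HMM parameters over chromatin marks."""

    marks: list[str]
    emissions: np.ndarray    # states x marks, in [0, 1]
    transitions: np.ndarray  # states x states, row-stochastic
    initial: np.ndarray      # states

    def __post_init__(self) -> None:
        S = self.emissions.shape[0]
        if self.emissions.shape[1] != len(self.marks):
            raise ValueError("emission matrix does not match mark list")
        if self.transitions.shape != (S, S) or self.initial.shape != (S,):
            raise ValueError("transition/initial shapes inconsistent with state count")
        if ((self.emissions < 0) | (self.emissions > 1)).any():
            raise ValueError("emissions must lie in [0, 1]")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return self.emissions.shape[0]


@dataclass
class Segmentation:
    """One chromatin state per bin; state ids are 1-based."""

    states: dict[str, np.ndarray]
    bin_size: int
    chrom_sizes: dict[str, int]
    n_states: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.states.items():
            if arr.min(initial=1) < 1 or arr.max(initial=1) > max(self.n_states, 1):
                raise ValueError(f"{chrom!r}: state ids outside [1, {self.n_states}]")

    @property
    def total_bins(self) -> int:
        return sum(len(a) for a in self.states.values())

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.states[c] for c in sorted(self.states)])


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

def poisson_cutoff(lam: float, p_threshold: float) -> int:
    """Smallest count c with upper-tail P(X >= c; lam) <= p_threshold."""
    if lam <= 0:
        return 1  # any positive count is "present" against a zero background
    c = np.arange(0, max(20, int(lam * 20)) + 2)
    tail = poisson.sf(c - 1, lam)  # P(X >= c)
    return int(c[tail <= p_threshold][0])


def binarize(
    tracks: Mapping[str, SignalTrack] | Sequence[SignalTrack],
    p_threshold: float = 1e-4,
) -> BinarizedMarks:
    """Call each mark present/absent per bin against a Poisson background.

    The background rate per mark is the genome-wide mean signal per bin;
    a bin is called present when its (rounded) count c satisfies
    P(X >= c; lambda) <= p_threshold.  A mark with zero signal everywhere
    is absent everywhere.
    """
    if not isinstance(tracks, Mapping):
        tracks = {t.mark: t for t in tracks}
    marks = list(tracks)
    ref = tracks[marks[0]]
    for t in tracks.values():
        if t.bin_size != ref.bin_size or t.chrom_sizes != ref.chrom_sizes:
            raise ValueError(f"track {t.mark!r} binning differs from {ref.mark!r}")
    calls = {}
    cutoffs = {}
    for mark in marks:
        counts_all = np.concatenate([tracks[mark].counts[c] for c in tracks[mark].counts])
        lam = counts_all.mean()
        cutoffs[mark] = poisson_cutoff(lam, p_threshold) if lam > 0 else None
    for chrom in ref.chrom_sizes:
        mat = np.zeros((len(tracks[marks[0]].counts[chrom]), len(marks)), dtype=np.uint8)
        for j, mark in enumerate(marks):
            if cutoffs[mark] is not None:
                mat[:, j] = np.rint(tracks[mark].counts[chrom]) >= cutoffs[mark]
        calls[chrom] = mat
    bm = BinarizedMarks(
        marks=marks, calls=calls, bin_size=ref.bin_size,
        chrom_sizes=dict(ref.chrom_sizes),
    )
    return bm


# ---------------------------------------------------------------------------
# Baum-Welch EM
# ---------------------------------------------------------------------------

def _emission_probs(x: np.ndarray, emissions: np.ndarray) -> np.ndarray:
    """B[t, s] = P(x_t | s) for binary observations x (T x M)."""
    logE, log1E = np.log(emissions), np.log1p(-emissions)
    return np.exp(x @ logE.T + (1 - x) @ log1E.T)


def _forward_backward(x, pi, T, E):
    """Scaled forward-backward for one sequence.

    Returns (loglik, gamma [TxS], xi_sum [SxS], alpha-scale consistency is
    internal).  gamma rows sum to 1 exactly under the scaling used.
    """
    B = _emission_probs(x, E)
    Tlen, S = B.shape
    alpha = np.empty((Tlen, S))
    c = np.empty(Tlen)
    a = pi * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, Tlen):
        a = (alpha[t - 1] @ T) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((Tlen, S))
    beta[-1] = 1.0
    for t in range(Tlen - 2, -1, -1):
        beta[t] = (T @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    xi_sum = T * (alpha[:-1].T @ (B[1:] * beta[1:] / c[1:, None]))
    return float(np.log(c).sum()), gamma, xi_sum


def _em_run(sequences, n_states, n_marks, rng, max_iter, tol):
    S, M = n_states, n_marks
    E = rng.uniform(0.1, 0.9, size=(S, M))
    T = np.full((S, S), 0.5 / S) + 0.5 * np.eye(S)
    T /= T.sum(axis=1, keepdims=True)
    pi = np.full(S, 1.0 / S)
    trace: list[float] = []
    for _ in range(max_iter):
        loglik = 0.0
        gamma_x = np.zeros((S, M))
        gamma_tot = np.zeros(S)
        xi_tot = np.zeros((S, S))
        pi_acc = np.zeros(S)
        for x in sequences:
            ll, gamma, xi = _forward_backward(x, pi, T, E)
            loglik += ll
            gamma_x += gamma.T @ x
            gamma_tot += gamma.sum(axis=0)
            xi_tot += xi
            pi_acc += gamma[0]
        trace.append(loglik)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
        E = np.clip(gamma_x / gamma_tot[:, None], _PARAM_FLOOR, 1 - _PARAM_FLOOR)
        T = xi_tot / np.clip(xi_tot.sum(axis=1, keepdims=True), _PARAM_FLOOR, None)
        T = np.clip(T, _PARAM_FLOOR, None)
        T /= T.sum(axis=1, keepdims=True)
        pi = np.clip(pi_acc / len(sequences), _PARAM_FLOOR, None)
        pi /= pi.sum()
    return E, T, pi, trace


def learn_model(
    binary: BinarizedMarks,
    n_states: int,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> tuple[ChromatinModel, list[list[float]]]:
    """Baum-Welch training of the Bernoulli-emission HMM.

    Chromosomes are treated as independent observation sequences.  The
    best of ``n_restarts`` seeded random initializations (by final
    log-likelihood) is returned together with every restart's
    log-likelihood trace; EM guarantees each trace is nondecreasing.
    States of the returned model are sorted by descending total emission
    mass so state ids are stable across runs.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if binary.total_bins < n_states:
        raise ValueError("fewer bins than states")
    sequences = [binary.calls[c].astype(float) for c in sorted(binary.calls)]
    M = len(binary.marks)
    if n_states == 1:
        # degenerate EM closed form: emissions are the column means
        x = np.vstack(sequences)
        E = np.clip(x.mean(axis=0, keepdims=True), _PARAM_FLOOR, 1 - _PARAM_FLOOR)
        model = ChromatinModel(binary.marks, E, np.ones((1, 1)), np.ones(1))
        ll = float(sum(np.log(_emission_probs(s, E)).sum() for s in sequences))
        return model, [[ll]]
    rng = np.random.default_rng(seed)
    best = None
    traces = []
    for _ in range(max(1, n_restarts)):
        E, T, pi, trace = _em_run(sequences, n_states, M, rng, max_iter, tol)
        traces.append(trace)
        if best is None or trace[-1] > best[3][-1]:
            best = (E, T, pi, trace)
    E, T, pi, _ = best
    order = np.argsort(-E.sum(axis=1), kind="stable")
    model = ChromatinModel(
        marks=list(binary.marks),
        emissions=E[order],
        transitions=T[np.ix_(order, order)],
        initial=pi[order],
    )
    return model, traces


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def _check_marks(model: ChromatinModel, binary: BinarizedMarks) -> None:
    if list(model.marks) != list(binary.marks):
        raise ValueError(
            f"mark mismatch: model {model.marks} vs data {binary.marks}"
        )


def posterior_marginals(model: ChromatinModel, binary: BinarizedMarks) -> dict[str, np.ndarray]:
    """Per-bin posterior state probabilities (rows sum to 1)."""
    _check_marks(model, binary)
    out = {}
    for chrom, mat in binary.calls.items():
        _, gamma, _ = _forward_backward(
            mat.astype(float), model.initial, model.transitions, model.emissions
        )
        out[chrom] = gamma
    return out


def sequence_loglik(model: ChromatinModel, binary: BinarizedMarks) -> float:
    """Total log-likelihood of the binarized data under the model."""
    _check_marks(model, binary)
    total = 0.0
    for mat in binary.calls.values():
        ll, _, _ = _forward_backward(
            mat.astype(float), model.initial, model.transitions, model.emissions
        )
        total += ll
    return total


def _viterbi(x, pi, T, E):
    B = np.log(_emission_probs(x, E))
    logT = np.log(T)
    Tlen, S = B.shape
    delta = np.empty((Tlen, S))
    back = np.zeros((Tlen, S), dtype=int)
    delta[0] = np.log(pi) + B[0]
    for t in range(1, Tlen):
        scores = delta[t - 1][:, None] + logT
        back[t] = scores.argmax(axis=0)
        delta[t] = scores.max(axis=0) + B[t]
    path = np.empty(Tlen, dtype=int)
    path[-1] = delta[-1].argmax()
    for t in range(Tlen - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def segment(
    model: ChromatinModel,
    binary: BinarizedMarks,
    rule: str = "posterior_max",
) -> Segmentation:
    """Assign each bin a state by maximum posterior (default) or Viterbi."""
    _check_marks(model, binary)
    states = {}
    if rule == "posterior_max":
        for chrom, gamma in posterior_marginals(model, binary).items():
            states[chrom] = gamma.argmax(axis=1) + 1
    elif rule == "viterbi":
        for chrom, mat in binary.calls.items():
            states[chrom] = _viterbi(
                mat.astype(float), model.initial, model.transitions, model.emissions
            ) + 1
    else:
        raise ValueError(f"unknown decoding rule {rule!r}")
    return Segmentation(
        states=states, bin_size=binary.bin_size,
        chrom_sizes=dict(binary.chrom_sizes), n_states=model.n_states,
        provenance={"rule": rule},
    )


# ---------------------------------------------------------------------------
# Model comparison & selection
# ---------------------------------------------------------------------------

def compare_models(
    candidate: ChromatinModel, reference: ChromatinModel
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Emission-vector similarity of each candidate state to a reference model.

    For each candidate state the Pearson correlation of its emission
    vector against every reference state's is computed and the maximum
    reported; a constant emission vector has no defined correlation
    (NaN).  The summary gives the median and min of the per-state maxima.
    """
    if list(candidate.marks) != list(reference.marks):
        raise ValueError("models are over different mark sets")

    def _corr(u, v):
        if np.ptp(u) == 0 or np.ptp(v) == 0:
            return np.nan
        return float(np.corrcoef(u, v)[0, 1])

    rows = []
    for i, evec in enumerate(candidate.emissions, start=1):
        corrs = [_corr(evec, rvec) for rvec in reference.emissions]
        finite = [c for c in corrs if not np.isnan(c)]
        best = max(finite) if finite else np.nan
        rows.append({
            "candidate_state": i,
            "max_correlation": best,
            "best_reference_state": (int(np.nanargmax(corrs)) + 1) if finite else -1,
        })
    df = pd.DataFrame(rows)
    return df, {
        "median": float(df["max_correlation"].median()),
        "min": float(df["max_correlation"].min()),
    }


def recommend_n_states(
    models: Mapping[int, ChromatinModel], gain_tol: float = 0.01
) -> tuple[int, pd.DataFrame]:
    """Heuristic model selection against the largest swept model.

    Every candidate is compared to the largest model by per-state max
    emission correlation.  An absolute similarity cutoff is a poor
    criterion here — an undersized model's blended emission vectors can
    still *correlate* highly with reference states because Pearson
    correlation is blind to magnitude — so the rule is saturation
    instead: pick the smallest model whose median similarity improves by
    less than ``gain_tol`` when one more state is allowed.  This is a
    heuristic, not a likelihood test; the full comparison table is
    returned for inspection.
    """
    reference = models[max(models)]
    rows = []
    for n in sorted(models):
        _, summary = compare_models(models[n], reference)
        rows.append({"n_states": n, "median_max_corr": summary["median"],
                     "min_max_corr": summary["min"]})
    table = pd.DataFrame(rows)
    medians = table["median_max_corr"].to_numpy()
    chosen = int(table["n_states"].iloc[-1])
    for i in range(len(table) - 1):
        if medians[i + 1] - medians[i] < gain_tol:
            chosen = int(table["n_states"].iloc[i])
            break
    return chosen, table


def match_states(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Optimal assignment of estimated emission rows to true rows.

    Minimizes total absolute emission difference (Hungarian algorithm);
    returns the permutation p with estimated[p[i]] matched to truth[i].
    """
    cost = np.abs(estimated[None, :, :] - truth[:, None, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(truth), dtype=int)
    perm[rows] = cols
    return perm


# ---------------------------------------------------------------------------
# Fold enrichment
# ---------------------------------------------------------------------------

@dataclass
class FoldEnrichmentTable:
    """fold[s, f] = (overlap/state_bins) / (feature_bins/total_bins)."""

    fold: pd.DataFrame          # states x (feature classes + marks)
    overlap_bins: pd.DataFrame  # same shape, raw overlap counts
    state_bins: pd.Series
    column_bins: pd.Series
    total_bins: int


def _rasterize(features: FeatureAnnotation, seg: Segmentation) -> dict[str, np.ndarray]:
    """Per feature class, boolean mask over bins (>= 1 bp overlap counts)."""
    masks: dict[str, np.ndarray] = {}
    bs = seg.bin_size
    bins_per_chrom = {c: len(seg.states[c]) for c in seg.states}
    for row in features.df.itertuples():
        if row.chrom not in bins_per_chrom:
            raise ValueError(f"feature on unknown chromosome {row.chrom!r}")
        mask = masks.setdefault(
            row.feature_class,
            {c: np.zeros(nb, dtype=bool) for c, nb in bins_per_chrom.items()},
        )
        first = row.start // bs
        last = min((row.end - 1) // bs, bins_per_chrom[row.chrom] - 1)
        mask[row.chrom][first:last + 1] = True
    return {
        fc: np.concatenate([m[c] for c in sorted(m)]) for fc, m in masks.items()
    }


def overlap_enrichment(
    seg: Segmentation,
    features: FeatureAnnotation,
    marks: BinarizedMarks | None = None,
) -> FoldEnrichmentTable:
    """Fold enrichment of every state over feature classes (and mark calls).

    fold(s, f) = [bins(s and f) / bins(s)] / [bins(f) / bins(genome)]; a
    state with zero bins yields an NA row.  When binarized marks are
    supplied, each mark's present-bins act as an additional column.
    """
    state_vec = seg.stacked()
    total = len(state_vec)
    columns: dict[str, np.ndarray] = dict(_rasterize(features, seg))
    if marks is not None:
        if marks.bin_size != seg.bin_size or sorted(marks.calls) != sorted(seg.states):
            raise ValueError("mark binning does not match the segmentation")
        stacked = marks.stacked().astype(bool)
        for j, mark in enumerate(marks.marks):
            columns[mark] = stacked[:, j]
    state_ids = list(range(1, seg.n_states + 1))
    fold = pd.DataFrame(index=[f"E{s}" for s in state_ids], columns=list(columns), dtype=float)
    overlap = fold.copy()
    state_bins = pd.Series(
        {f"E{s}": int((state_vec == s).sum()) for s in state_ids}, dtype=int
    )
    col_bins = pd.Series({f: int(m.sum()) for f, m in columns.items()}, dtype=int)
    for s in state_ids:
        in_state = state_vec == s
        ns = state_bins[f"E{s}"]
        for f, m in columns.items():
            k = int((in_state & m).sum())
            overlap.loc[f"E{s}", f] = k
            nf = col_bins[f]
            if ns == 0 or nf == 0:
                fold.loc[f"E{s}", f] = np.nan
            else:
                fold.loc[f"E{s}", f] = (k / ns) / (nf / total)
    return FoldEnrichmentTable(
        fold=fold, overlap_bins=overlap,
        state_bins=state_bins, column_bins=col_bins, total_bins=total,
    )
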