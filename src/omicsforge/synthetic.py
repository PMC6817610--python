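"""Seeded generators for every input the pipeline consumes, with planted truth.

Each generator is a pure function of its arguments (including the seed)
and returns, alongside the generated object, a :class:`SimulationTruth`
recording the planted structure so recovery can be checked end to end:
co-expression modules driven by shared latent factors, GO-like gene sets
mirroring those modules, promoters with a motif planted in a foreground
gene set, and chromatin signal tracks emitted by a known hidden Markov
chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    FeatureAnnotation,
    GeneSetCollection,
    MotifLibrary,
    SignalTrack,
)
from .motifs import PromoterSet

__all__ = [
    "SimulationTruth",
    "simulate_expression",
    "simulate_gene_sets",
    "simulate_promoters",
    "simulate_chromatin",
    "random_motif_library",
]


@dataclass
class SimulationTruth:
    """Planted ground truth; fields are populated by the relevant generator."""

    seed: int
    modules: dict[str, list[str]] | None = None
    all_genes: list[str] | None = None
    motif: str | None = None
    foreground: list[str] | None = None
    planted_per_promoter: int | None = None
    hmm_emissions: list[list[float]] | None = None
    hmm_transitions: list[list[float]] | None = None
    state_path: list[int] | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {k: v for k, v in asdict(self).items() if v is not None}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def simulate_expression(
    n_genes: int = 200,
    n_samples: int = 200,
    n_modules: int = 10,
    module_size: int = 8,
    within_corr: float = 0.9,
    noise_sd: float = 1.0,
    seed: int = 1,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """FPKM-like expression matrix with planted co-expression modules.

    Each module shares a latent per-sample profile z; a member gene's
    log2 expression is sqrt(rho) * z + sqrt(1 - rho) * noise_sd * eps,
    so with unit noise_sd the expected within-module Pearson correlation
    on the log scale is exactly ``within_corr``.  Log values are shifted
    by +5 and exponentiated base 2, giving lognormal-like FPKM whose
    log2(FPKM + 1) transform is essentially the generating Gaussian.
    Background genes are independent noise.
    """
    if not 0 <= within_corr <= 1:
        raise ValueError(f"within_corr must be in [0, 1], got {within_corr}")
    if n_modules * module_size > n_genes:
        raise ValueError("planted modules do not fit into n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    log_expr = np.empty((n_genes, n_samples))
    modules: dict[str, list[str]] = {}
    g = 0
    for m in range(n_modules):
        latent = rng.standard_normal(n_samples)
        members = []
        for _ in range(module_size):
            eps = rng.standard_normal(n_samples)
            log_expr[g] = (
                np.sqrt(within_corr) * latent
                + np.sqrt(1 - within_corr) * noise_sd * eps
            )
            members.append(genes[g])
            g += 1
        modules[f"MOD{m + 1}"] = members
    log_expr[g:] = rng.standard_normal((n_genes - g, n_samples))
    fpkm = np.exp2(log_expr + 5.0)
    matrix = ExpressionMatrix(pd.DataFrame(fpkm, index=genes, columns=samples))
    return matrix, SimulationTruth(seed=seed, modules=modules, all_genes=genes)


def simulate_gene_sets(
    truth: SimulationTruth,
    extra_terms: int = 20,
    size_range: tuple[int, int] = (4, 20),
    seed: int = 2,
) -> GeneSetCollection:
    """GO-like collection: one term per planted module plus random decoys.

    Module terms are subsampled into ``size_range`` when needed; decoy
    terms draw members uniformly from all simulated genes and carry no
    correlation structure.
    """
    if not truth.modules:
        raise ValueError("truth contains no planted modules")
    lo, hi = size_range
    rng = np.random.default_rng(seed)
    collection = GeneSetCollection()
    for name, members in truth.modules.items():
        if len(members) < lo:
            raise ValueError(f"module {name} smaller than minimum term size {lo}")
        chosen = members
        if len(members) > hi:
            chosen = list(rng.choice(members, size=hi, replace=False))
        collection.add(f"TERM_{name}", f"planted module {name}", chosen)
    universe = truth.all_genes or sorted({g for m in truth.modules.values() for g in m})
    for d in range(extra_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        collection.add(f"DECOY{d + 1}", "random decoy term", members)
    return collection


def simulate_promoters(
    n_genes: int = 500,
    length: int = 3000,
    gc: float = 0.4,
    motif: str = "TGACGTCA",
    foreground: int | list[str] = 50,
    planted_per_promoter: int = 2,
    seed: int = 3,
) -> tuple[PromoterSet, SimulationTruth]:
    """Random promoters with a motif planted in a foreground gene set.

    Background bases are i.i.d. at the given GC content; every foreground
    promoter receives exactly ``planted_per_promoter`` non-overlapping
    copies of the (non-degenerate) motif at seeded positions.
    """
    motif = motif.upper()
    if len(motif) >= length:
        raise ValueError("motif longer than the promoter")
    if set(motif) - set("ACGT"):
        raise ValueError("planted motif must be a concrete A/C/G/T sequence")
    rng = np.random.default_rng(seed)
    genes = [f"P{i + 1:04d}" for i in range(n_genes)]
    if isinstance(foreground, int):
        fg = sorted(rng.choice(genes, size=foreground, replace=False))
    else:
        fg = sorted(map(str, foreground))
        if set(fg) - set(genes):
            raise ValueError("foreground gene ids outside the simulated universe")
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = np.array(list("ACGT"))
    if planted_per_promoter * len(motif) > length:
        raise ValueError("cannot place the requested copies without overlap")
    sequences: dict[str, str] = {}
    fg_set = set(fg)
    for gene in genes:
        seq = rng.choice(bases, size=length, p=probs)
        if gene in fg_set:
            positions: list[int] = []
            while len(positions) < planted_per_promoter:
                pos = int(rng.integers(0, length - len(motif) + 1))
                if all(abs(pos - q) >= len(motif) for q in positions):
                    positions.append(pos)
            for pos in positions:
                seq[pos:pos + len(motif)] = list(motif)
        sequences[gene] = "".join(seq)
    truth = SimulationTruth(
        seed=seed, motif=motif, foreground=fg,
        planted_per_promoter=planted_per_promoter, all_genes=genes,
    )
    return PromoterSet(sequences, nominal_length=length), truth


def random_motif_library(
    n_motifs: int = 20,
    length_range: tuple[int, int] = (6, 10),
    degenerate_fraction: float = 0.2,
    seed: int = 0,
    planted: dict[str, str] | None = None,
) -> MotifLibrary:
    """Decoy consensus motifs (optionally alongside planted ones).

    Decoys mix concrete bases with occasional 2-fold degenerate codes,
    mimicking the consensus catalogs used for promoter scanning.
    """
    rng = np.random.default_rng(seed)
    concrete = list("ACGT")
    twofold = list("RYSWKM")
    motifs: dict[str, str] = dict(planted or {})
    i = 0
    while len(motifs) < n_motifs + len(planted or {}):
        i += 1
        size = int(rng.integers(length_range[0], length_range[1] + 1))
        letters = [
            (rng.choice(twofold) if rng.random() < degenerate_fraction
             else rng.choice(concrete))
            for _ in range(size)
        ]
        consensus = "".join(letters)
        if consensus not in motifs.values():
            motifs[f"DECOY{i:03d}"] = consensus
    return MotifLibrary(motifs)


_DEFAULT_EMISSIONS = np.array([
    [0.95, 0.05, 0.90, 0.10],   # active: accessible + active marks
    [0.05, 0.90, 0.10, 0.80],   # repressed: silencing marks
    [0.02, 0.05, 0.03, 0.10],   # quiescent: little of anything
])
_DEFAULT_TRANSITIONS = np.array([
    [0.80, 0.10, 0.10],
    [0.10, 0.80, 0.10],
    [0.025, 0.025, 0.95],       # quiescent state dominates the genome
])
_DEFAULT_MARKS = ("DHS", "H3K27me3", "H3K4me3", "mCG")


def simulate_chromatin(
    n_bins: int = 20000,
    marks: tuple[str, ...] = _DEFAULT_MARKS,
    n_states: int = 3,
    emissions: np.ndarray | None = None,
    transitions: np.ndarray | None = None,
    initial: np.ndarray | None = None,
    lambda_high: float = 30.0,
    lambda_low: float = 0.1,
    bin_size: int = 200,
    chrom: str = "chr1",
    seed: int = 7,
) -> tuple[dict[str, SignalTrack], FeatureAnnotation, SimulationTruth]:
    """Per-mark signal tracks emitted by a known hidden Markov chain.

    A state path is sampled from the chain; given the state, each mark is
    present in a bin with its emission probability, and bin counts are
    Poisson(lambda_high) where present, Poisson(lambda_low) where absent.
    The default signal-to-noise (30 vs 0.1 expected counts) reflects
    strong, well-enriched marks and keeps Poisson-threshold binarization
    near-perfectly sensitive.  Bins occupied by the first state are also
    emitted as "promoter" feature intervals for enrichment tests.
    """
    E = _DEFAULT_EMISSIONS if emissions is None else np.asarray(emissions, dtype=float)
    T = _DEFAULT_TRANSITIONS if transitions is None else np.asarray(transitions, dtype=float)
    if E.shape != (n_states, len(marks)):
        raise ValueError(f"emissions shape {E.shape} != ({n_states}, {len(marks)})")
    if T.shape != (n_states, n_states) or not np.allclose(T.sum(axis=1), 1.0):
        raise ValueError("transitions must be a row-stochastic n_states x n_states matrix")
    pi = np.full(n_states, 1.0 / n_states) if initial is None else np.asarray(initial, float)
    if lambda_high <= lambda_low:
        raise ValueError("lambda_high must exceed lambda_low")
    rng = np.random.default_rng(seed)

    path = np.empty(n_bins, dtype=int)
    path[0] = rng.choice(n_states, p=pi)
    for t in range(1, n_bins):
        path[t] = rng.choice(n_states, p=T[path[t - 1]])
    present = rng.random((n_bins, len(marks))) < E[path]
    counts = np.where(
        present,
        rng.poisson(lambda_high, size=present.shape),
        rng.poisson(lambda_low, size=present.shape),
    ).astype(float)

    chrom_sizes = {chrom: n_bins * bin_size}
    tracks = {
        mark: SignalTrack(mark, dict(chrom_sizes), bin_size, {chrom: counts[:, j].copy()})
        for j, mark in enumerate(marks)
    }
    records = []
    in_state = np.flatnonzero(path == 0)
    if in_state.size:
        run_start = in_state[0]
        prev = in_state[0]
        for b in list(in_state[1:]) + [None]:
            if b is None or b != prev + 1:
                records.append({
                    "chrom": chrom,
                    "start": int(run_start) * bin_size,
                    "end": (int(prev) + 1) * bin_size,
                    "feature_class": "promoter",
                    "strand": None, "gene_id": None,
                })
                run_start = b
            prev = b
    features = FeatureAnnotation.from_records(records)
    truth = SimulationTruth(
        seed=seed,
        hmm_emissions=E.tolist(),
        hmm_transitions=T.tolist(),
        state_path=path.tolist(),
        extra={"marks": list(marks), "lambda_high": lambda_high,
               "lambda_low": lambda_low, "bin_size": bin_size, "chrom": chrom},
    )
    return tracks, features, truth
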