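"""Promoter extraction and consensus-motif enrichment against a resampled background.

Promoters are the 3,000 bp immediately upstream of the TSS, read 5'->3'
on the gene's strand.  A motif's enrichment in a query of m genes is
scored against the empirical distribution of its total count in random
draws of m genes from the promoter universe:

    Z = (N_motif - mean_motif) / stdev_motif
    P = 1 - Phi(N_motif; mean_motif, stdev_motif)

where mean/stdev are taken over the (default 1,000) background draws.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy.stats import norm

from .io import IUPAC_CODES, FeatureAnnotation, MotifLibrary, validate_iupac

__all__ = [
    "PromoterSet",
    "extract_promoters",
    "count_motif",
    "motif_enrichment",
    "z_and_p",
    "iupac_to_regex",
    "iupac_reverse_complement",
    "reverse_complement",
    "read_promoters_fasta",
    "write_promoters_fasta",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterSet:
    """gene id -> uppercase promoter sequence (A/C/G/T/N), strand-resolved."""

    sequences: dict[str, str]
    nominal_length: int = 3000
    truncated: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            if len(seq) > self.nominal_length:
                raise ValueError(
                    f"promoter of {gene!r} longer ({len(seq)}) than nominal "
                    f"{self.nominal_length}"
                )
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"promoter of {gene!r} has symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)


def extract_promoters(
    genome: str | Path | Fasta,
    annotation: FeatureAnnotation,
    length: int = 3000,
) -> PromoterSet:
    """Strand-aware upstream promoter extraction from a genome FASTA.

    For a + strand gene the promoter is [TSS - length, TSS) on the
    forward strand; for a - strand gene it is [gene_end, gene_end + length)
    reverse-complemented, so every sequence reads 5'->3' toward the TSS.
    Promoters truncated at a chromosome edge are kept and flagged.
    """
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    sequences: dict[str, str] = {}
    truncated: set[str] = set()
    for row in annotation.df.itertuples():
        gene = row.gene_id
        if gene is None or (isinstance(gene, float) and np.isnan(gene)):
            continue
        if row.strand not in ("+", "-"):
            raise ValueError(f"gene {gene!r} has no usable strand ({row.strand!r})")
        if row.chrom not in fasta:
            raise ValueError(f"chromosome {row.chrom!r} missing from FASTA")
        chrom_len = len(fasta[row.chrom])
        if row.strand == "+":
            start, end = max(0, row.start - length), row.start
            seq = str(fasta[row.chrom][start:end]).upper()
        else:
            start, end = row.end, min(chrom_len, row.end + length)
            seq = reverse_complement(str(fasta[row.chrom][start:end]).upper())
        if len(seq) < length:
            truncated.add(str(gene))
        sequences[str(gene)] = seq
    return PromoterSet(sequences, nominal_length=length, truncated=truncated)


def iupac_to_regex(consensus: str) -> re.Pattern:
    """Compile an IUPAC consensus into an overlap-counting regex.

    Each degenerate code becomes a character class over A/C/G/T only, so
    an N in the *sequence* never matches; the whole pattern is wrapped in
    a lookahead so overlapping occurrences are all counted.
    """
    consensus = validate_iupac(consensus)
    classes = "".join(
        c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]" for c in consensus
    )
    return re.compile(f"(?={classes})")


_CODE_BY_SET = {frozenset(v): k for k, v in IUPAC_CODES.items()}
_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def iupac_reverse_complement(consensus: str) -> str:
    """Reverse complement of a degenerate consensus (R -> Y, W -> W, ...)."""
    return "".join(
        _CODE_BY_SET[frozenset(_BASE_COMPLEMENT[b] for b in IUPAC_CODES[c])]
        for c in reversed(validate_iupac(consensus))
    )


def count_motif(
    promoters: PromoterSet, motif: str, both_strands: bool = False
) -> tuple[int, dict[str, int]]:
    """Occurrences of a consensus motif in each promoter (overlaps counted).

    Matching is on the promoter strand only by default; ``both_strands``
    additionally counts matches of the reverse complement pattern (useful
    for unstranded motif semantics, at the cost of double-counting
    palindromes).
    """
    patterns = [iupac_to_regex(motif)]
    if both_strands:
        patterns.append(iupac_to_regex(iupac_reverse_complement(motif)))
    per_gene = {}
    for gene, seq in promoters.sequences.items():
        per_gene[gene] = sum(len(p.findall(seq)) for p in patterns)
    return sum(per_gene.values()), per_gene


def z_and_p(n_observed: float, mean: float, stdev: float) -> tuple[float, float]:
    """Z = (N - mean) / stdev and the normal upper-tail P = 1 - Phi(Z).

    The background mean/stdev come from the random gene draws; stdev 0
    (motif absent from every draw) yields NaN for both.
    """
    if stdev <= 0:
        return float("nan"), float("nan")
    z = (n_observed - mean) / stdev
    return z, float(norm.sf(z))


def motif_enrichment(
    query_genes: list[str],
    promoters_all: PromoterSet,
    library: MotifLibrary,
    n_draws: int = 1000,
    seed: int = 0,
    both_strands: bool = False,
) -> pd.DataFrame:
    """Z-score / P-value enrichment of every library motif in the query promoters.

    The background for a query of m genes is ``n_draws`` seeded draws of
    m genes without replacement from the whole promoter universe; each
    motif's background mean and population stdev (ddof=0) feed the Z and
    the normal upper-tail P.  Motifs absent from every draw (stdev 0) are
    reported with NaN Z/P.  Returns a DataFrame sorted by descending Z.
    """
    universe = promoters_all.gene_ids
    m = len(set(query_genes))
    if m < 2:
        raise ValueError("need >= 2 query genes")
    missing = sorted(set(query_genes) - set(universe))
    if missing:
        raise ValueError(f"query genes without promoters: {missing[:5]}")
    if m > len(universe):
        raise ValueError("query larger than the promoter universe")

    motif_ids = list(library.motifs)
    # per-gene count matrix (genes x motifs): background draws reduce to row sums
    counts = np.zeros((len(universe), len(motif_ids)), dtype=np.int64)
    for j, motif_id in enumerate(motif_ids):
        _, per_gene = count_motif(promoters_all, library.motifs[motif_id], both_strands)
        counts[:, j] = [per_gene[g] for g in universe]
    gene_index = {g: i for i, g in enumerate(universe)}
    query_rows = [gene_index[g] for g in sorted(set(query_genes))]
    observed = counts[query_rows].sum(axis=0)

    rng = np.random.default_rng(seed)
    draws = np.empty((n_draws, len(motif_ids)), dtype=np.int64)
    for d in range(n_draws):
        rows = rng.choice(len(universe), size=m, replace=False)
        draws[d] = counts[rows].sum(axis=0)
    mean = draws.mean(axis=0)
    stdev = draws.std(axis=0, ddof=0)

    zp = [z_and_p(o, mu, sd) for o, mu, sd in zip(observed, mean, stdev)]
    z = np.array([v[0] for v in zp])
    p = np.array([v[1] for v in zp])
    df = pd.DataFrame({
        "motif_id": motif_ids,
        "consensus": [library.motifs[mid] for mid in motif_ids],
        "N_motif": observed,
        "mean_motif": mean,
        "stdev_motif": stdev,
        "z_score": z,
        "p_value": p,
        "n_draws": n_draws,
    })
    return df.sort_values("z_score", ascending=False, kind="mergesort").reset_index(drop=True)


def read_promoters_fasta(path: str | Path, nominal_length: int = 3000) -> PromoterSet:
    """Read one promoter sequence per gene from a FASTA file."""
    sequences: dict[str, str] = {}
    gene = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if gene is not None:
                    sequences[gene] = "".join(chunks).upper()
                gene = line[1:].split()[0]
                if gene in sequences:
                    raise ValueError(f"duplicate promoter for gene {gene!r}")
                chunks = []
            elif line:
                chunks.append(line)
    if gene is not None:
        sequences[gene] = "".join(chunks).upper()
    return PromoterSet(sequences, nominal_length=nominal_length)


def write_promoters_fasta(promoters: PromoterSet, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for gene, seq in promoters.sequences.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
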