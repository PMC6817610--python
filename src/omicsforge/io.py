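"""Domain types and readers/writers for the standard formats the pipeline touches.

All interval I/O uses BED-style 0-based half-open coordinates; 1-based
inputs (GFF-style) must be converted by the caller at parse time.  Gene
identifiers are case-sensitive opaque strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "FeatureAnnotation",
    "SignalTrack",
    "MotifLibrary",
    "FEATURE_CLASSES",
    "IUPAC_CODES",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_feature_bed",
    "read_signal_bedgraph",
    "read_motif_library",
    "write_motif_library",
    "write_segmentation_bed",
    "read_segmentation_bed",
]

FEATURE_CLASSES = frozenset(
    {"promoter", "5'UTR", "exon", "intron", "3'UTR", "intergenic", "TE", "custom"}
)

#: Degenerate nucleotide alphabet for consensus motifs.
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of nonnegative FPKM-like expression values."""

    data: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(values).any():
            g, s = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at gene {idx[g]!r}, sample {cols[s]!r}; "
                "missing expression values are not accepted"
            )
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(f"negative value at gene {idx[g]!r}, sample {cols[s]!r}")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.term_id!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Named term -> member-gene sets (GO terms, modules, pathway sets)."""

    terms: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, gs in self.terms.items():
            if term_id != gs.term_id:
                raise ValueError(f"key {term_id!r} does not match term id {gs.term_id!r}")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.terms[term_id]

    def add(self, term_id: str, name: str, genes: Iterable[str]) -> None:
        if term_id in self.terms:
            raise ValueError(f"duplicate term id {term_id!r}")
        self.terms[term_id] = GeneSet(term_id, name, frozenset(map(str, genes)))


@dataclass
class FeatureAnnotation:
    """Genomic feature intervals, 0-based half-open.

    ``df`` columns: chrom, start, end, feature_class, strand, gene_id
    (gene_id may be None/NaN for features not tied to a gene).
    """

    df: pd.DataFrame

    REQUIRED = ("chrom", "start", "end", "feature_class", "strand", "gene_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        bad = self.df[self.df["start"] >= self.df["end"]]
        if len(bad):
            r = bad.iloc[0]
            raise ValueError(f"empty/inverted interval {r.chrom}:{r.start}-{r.end}")
        classes = set(self.df["feature_class"].unique())
        unknown = classes - FEATURE_CLASSES
        if unknown:
            raise ValueError(
                f"unknown feature classes {sorted(unknown)}; "
                f"allowed: {sorted(FEATURE_CLASSES)}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "FeatureAnnotation":
        records = list(records)
        if not records:
            return cls(pd.DataFrame(columns=list(cls.REQUIRED)))
        df = pd.DataFrame(records)
        for col in ("strand", "gene_id"):
            if col not in df.columns:
                df[col] = None
        return cls(df[list(cls.REQUIRED)])


@dataclass
class SignalTrack:
    """Per-bin signal for one chromatin mark over fixed-width genome bins.

    Bins tile each chromosome without gaps or overlap; the last bin may be
    shorter than ``bin_size``.
    """

    mark: str
    chrom_sizes: dict[str, int]
    bin_size: int
    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, size in self.chrom_sizes.items():
            expected = n_bins(size, self.bin_size)
            arr = self.counts.get(chrom)
            if arr is None:
                raise ValueError(f"no bins for chromosome {chrom!r}")
            if len(arr) != expected:
                raise ValueError(
                    f"{chrom!r}: {len(arr)} bins, expected {expected} "
                    f"for size {size} at bin_size {self.bin_size}"
                )
            if (np.asarray(arr) < 0).any():
                raise ValueError(f"negative signal on {chrom!r}")

    @property
    def total_bins(self) -> int:
        return sum(len(a) for a in self.counts.values())


@dataclass
class MotifLibrary:
    """motif id -> IUPAC consensus string."""

    motifs: dict[str, str]

    def __post_init__(self) -> None:
        for motif_id, consensus in self.motifs.items():
            validate_iupac(consensus, context=motif_id)

    def __len__(self) -> int:
        return len(self.motifs)

    def items(self):
        return self.motifs.items()


def validate_iupac(consensus: str, min_length: int = 4, context: str = "") -> str:
    """Check a consensus string against the IUPAC alphabet; return it uppercased."""
    consensus = consensus.upper()
    where = f" in motif {context!r}" if context else ""
    if len(consensus) < min_length:
        raise ValueError(f"consensus {consensus!r}{where} shorter than {min_length}")
    bad = set(consensus) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"invalid IUPAC symbol(s) {sorted(bad)}{where}")
    return consensus


def n_bins(chrom_size: int, bin_size: int) -> int:
    return max(1, math.ceil(chrom_size / bin_size))


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated genes x samples table.

    First column holds gene ids, header row holds sample ids, body is
    numeric.  Duplicate ids, ragged rows and non-numeric cells are
    reported with row/column context.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_fields = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != n_fields:
                raise ValueError(
                    f"{path.name}:{lineno}: ragged row "
                    f"({len(line.rstrip(chr(10)).split(chr(9)))} fields, expected {n_fields})"
                )
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"{path.name}: non-numeric cell at gene {gene!r}, sample {col!r}"
            )
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term, description, members, tab-separated."""
    path = Path(path)
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            term_id, name = fields[0], fields[1]
            members = [g for g in fields[2:] if g]
            if not members:
                raise ValueError(f"{path.name}:{lineno}: term {term_id!r} has no members")
            collection.add(term_id, name, members)
    return collection


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.term_id, gs.name, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Feature annotations (BED)
# ---------------------------------------------------------------------------

def read_feature_bed(path: str | Path, feature_class: str = "custom") -> FeatureAnnotation:
    """Read BED intervals (>= 3 columns; name -> gene_id, col 6 -> strand)."""
    records = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path.name}:{lineno}: BED line needs >= 3 fields")
            records.append({
                "chrom": f[0],
                "start": int(f[1]),
                "end": int(f[2]),
                "feature_class": feature_class,
                "strand": f[5] if len(f) > 5 else None,
                "gene_id": f[3] if len(f) > 3 and f[3] != "." else None,
            })
    return FeatureAnnotation.from_records(records) if records else FeatureAnnotation(
        pd.DataFrame(columns=list(FeatureAnnotation.REQUIRED))
    )


# ---------------------------------------------------------------------------
# bedGraph -> binned SignalTrack
# ---------------------------------------------------------------------------

def read_signal_bedgraph(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 200,
    mark: str | None = None,
    mode: str = "coverage",
) -> SignalTrack:
    """Aggregate bedGraph intervals into fixed genome bins.

    mode="coverage": per-bin signal = sum(value * overlap-bp) / bin_size
    (mean-coverage semantics).  mode="counts": each interval's value is
    attributed entirely to the bin containing its midpoint.
    Uncovered bins are 0.
    """
    if mode not in ("coverage", "counts"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    path = Path(path)
    bins = {
        chrom: np.zeros(n_bins(size, bin_size)) for chrom, size in chrom_sizes.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e, v = line.split("\t")[:4]
            start, end, value = int(s), int(e), float(v)
            if chrom not in chrom_sizes:
                raise ValueError(f"{path.name}:{lineno}: unknown chromosome {chrom!r}")
            if end > chrom_sizes[chrom]:
                raise ValueError(
                    f"{path.name}:{lineno}: interval end {end} beyond "
                    f"{chrom!r} size {chrom_sizes[chrom]}"
                )
            if value < 0:
                raise ValueError(f"{path.name}:{lineno}: negative value {value}")
            arr = bins[chrom]
            if mode == "counts":
                arr[((start + end) // 2) // bin_size] += value
            else:
                first, last = start // bin_size, (end - 1) // bin_size
                for b in range(first, last + 1):
                    lo, hi = max(start, b * bin_size), min(end, (b + 1) * bin_size)
                    arr[b] += value * (hi - lo) / bin_size
    return SignalTrack(mark or path.stem, dict(chrom_sizes), bin_size, bins)


# ---------------------------------------------------------------------------
# Motif libraries
# ---------------------------------------------------------------------------

def read_motif_library(path: str | Path) -> MotifLibrary:
    """Read a tab-separated motif table: motif_id, IUPAC consensus[, source]."""
    motifs: dict[str, str] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path.name}:{lineno}: need motif_id and consensus")
            motif_id = fields[0]
            if motif_id in motifs:
                raise ValueError(f"{path.name}:{lineno}: duplicate motif id {motif_id!r}")
            motifs[motif_id] = fields[1].upper()
    return MotifLibrary(motifs)


def write_motif_library(library: MotifLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for motif_id, consensus in library.items():
            fh.write(f"{motif_id}\t{consensus}\n")


# ---------------------------------------------------------------------------
# Segmentations (BED4)
# ---------------------------------------------------------------------------

def write_segmentation_bed(segmentation, path: str | Path) -> None:
    """Write per-bin chromatin states as merged BED4 (chrom, start, end, E<state>).

    Adjacent bins in the same state are merged into one line; coordinates
    are 0-based half-open and clipped to the chromosome end.
    """
    bs = segmentation.bin_size
    with open(path, "w") as fh:
        for chrom in sorted(segmentation.states):
            states = segmentation.states[chrom]
            size = segmentation.chrom_sizes[chrom]
            run_start = 0
            for i in range(1, len(states) + 1):
                if i == len(states) or states[i] != states[run_start]:
                    start = run_start * bs
                    end = min(i * bs, size)
                    fh.write(f"{chrom}\t{start}\t{end}\tE{states[run_start]}\n")
                    run_start = i


def read_segmentation_bed(path: str | Path, bin_size: int, chrom_sizes: Mapping[str, int]):
    """Read a BED4 segmentation back into per-bin state calls."""
    from .chromatin import Segmentation  # deferred: io stays import-light

    states = {
        chrom: np.zeros(n_bins(size, bin_size), dtype=int)
        for chrom, size in chrom_sizes.items()
    }
    n_states = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e, label = line.rstrip("\n").split("\t")[:4]
            state = int(label.lstrip("E"))
            n_states = max(n_states, state)
            first = int(s) // bin_size
            last = (int(e) - 1) // bin_size
            states[chrom][first:last + 1] = state
    return Segmentation(
        states=states, bin_size=bin_size,
        chrom_sizes=dict(chrom_sizes), n_states=n_states,
    )
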