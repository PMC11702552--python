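"""Core data types and coordinate conventions.

All genomic coordinates in this package are 0-based, half-open intervals
(BED convention).  The transcription start site (TSS) of a minus-strand
gene is its larger coordinate.  Readers in :mod:`dielscan.io` assert these
conventions and reject anything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "TimeSeriesExpression",
    "PanGene",
    "MotifPFM",
    "promoter_window",
    "size_factors",
    "validate_haplotype_table",
    "validate_snp_table",
    "HAPLOTYPE_COLUMNS",
    "SNP_COLUMNS",
]

#: required column order of a haplotype table
HAPLOTYPE_COLUMNS = ("pangene_id", "genotype_id", "haplotype_id")

#: required leading columns of a SNP table ("pvalue" may be NaN; genotype
#: dosage columns, if present, follow and are prefixed ``gt_``)
SNP_COLUMNS = ("snp_id", "chrom", "pos", "maf", "pvalue")


@dataclass(frozen=True)
class GeneRecord:
    """A gene with an annotated TSS on a 0-based, half-open interval."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    gene_start: int
    gene_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )
        if not self.gene_start < self.gene_end:
            raise ValueError(
                f"gene {self.gene_id}: gene_start must be < gene_end "
                f"(got [{self.gene_start}, {self.gene_end}))"
            )
        if not (self.gene_start <= self.tss <= self.gene_end):
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} outside "
                f"[{self.gene_start}, {self.gene_end}]"
            )


@dataclass
class TimeSeriesExpression:
    """Normalized abundance of one gene in one genotype over a diel course.

    ``times`` and ``values`` are flat, equal-length arrays; replicate
    observations share a time value and are distinguished by ``replicate``.
    Missing timepoints are simply absent — every statistic operates on the
    observed (t, y) pairs.
    """

    gene_id: str
    genotype_id: str
    times: np.ndarray
    values: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if np.any(self.values < 0):
            raise ValueError("normalized abundance must be non-negative")
        if self.replicate is None:
            self.replicate = np.zeros(len(self.times), dtype=int)
        else:
            self.replicate = np.asarray(self.replicate, dtype=int)
            if self.replicate.shape != self.times.shape:
                raise ValueError("replicate labels must match times in length")
        # within a replicate, times must be strictly increasing
        for rep in np.unique(self.replicate):
            t = self.times[self.replicate == rep]
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"times not strictly increasing within replicate {rep}"
                )

    @property
    def n_obs(self) -> int:
        return len(self.times)

    def timepoint_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique times and the replicate-averaged value at each."""
        t_unique, inverse = np.unique(self.times, return_inverse=True)
        sums = np.bincount(inverse, weights=self.values)
        counts = np.bincount(inverse)
        return t_unique, sums / counts


@dataclass(frozen=True)
class PanGene:
    """A homology group: one allele per genome assembly it is present in."""

    pangene_id: str
    members: dict = field(default_factory=dict)  # genotype_id -> gene_id

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError(f"pangene {self.pangene_id} has no members")
        gene_ids = list(self.members.values())
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError(
                f"pangene {self.pangene_id}: member gene_ids not unique"
            )

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class MotifPFM:
    """Position frequency matrix, rows A, C, G, T, columns positions."""

    matrix: np.ndarray
    name: str = ""
    n_sites: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("PFM must be a 4 x W matrix (rows A,C,G,T)")
        if self.matrix.shape[1] < 4:
            raise ValueError("PFM width must be >= 4")
        colsums = self.matrix.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValueError("PFM columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))

    def reverse_complement(self) -> "MotifPFM":
        return MotifPFM(self.matrix[::-1, ::-1].copy(),
                        name=self.name + "_rc", n_sites=self.n_sites)


def promoter_window(gene: GeneRecord, upstream: int = 1000,
                    downstream: int = 500) -> tuple[str, int, int, str]:
    """Promoter interval around the TSS, 0-based half-open.

    Plus strand: ``[tss - upstream, tss + downstream)``; minus strand the
    mirror image, with the sequence to be reverse-complemented by the
    caller.  The window is truncated at the chromosome start (coordinates
    never go negative).
    """
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    elif gene.strand == "-":
        start, end = gene.tss - downstream, gene.tss + upstream
    else:  # pragma: no cover - GeneRecord already validates
        raise ValueError(f"unknown strand {gene.strand!r}")
    return gene.chrom, max(start, 0), end, gene.strand


def size_factors(counts) -> np.ndarray:
    """Median-of-ratios size factors for a gene x sample count matrix.

    Reference genes are those with no zero count in any sample; each
    sample's factor is the median across reference genes of the ratio of
    its count to the gene's geometric mean across samples.

    Parameters
    ----------
    counts : array-like or DataFrame, shape (n_genes, n_samples)

    Returns
    -------
    ndarray of positive floats, one per sample (a Series if the input was
    a DataFrame).
    """
    is_frame = isinstance(counts, pd.DataFrame)
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2:
        raise ValueError("counts must be a 2-D gene x sample matrix")
    if np.any(mat < 0):
        raise ValueError("counts must be non-negative")
    reference = np.all(mat > 0, axis=1)
    if not np.any(reference):
        raise ValueError("no reference genes (every gene has a zero count)")
    ref = mat[reference]
    log_geo_mean = np.mean(np.log(ref), axis=1, keepdims=True)
    log_ratios = np.log(ref) - log_geo_mean
    factors = np.exp(np.median(log_ratios, axis=0))
    if is_frame:
        return pd.Series(factors, index=counts.columns, name="size_factor")
    return factors


def validate_haplotype_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the (pangene, genotype, haplotype) table invariants."""
    missing = [c for c in HAPLOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"haplotype table missing columns: {missing}")
    dup = df.duplicated(subset=["pangene_id", "genotype_id"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ValueError(
            "multiple haplotypes for "
            f"({first.pangene_id}, {first.genotype_id})"
        )
    return df


def validate_snp_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check SNP table invariants: sorted positions, MAF and p in range."""
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    if not np.issubdtype(df["pos"].dtype, np.integer):
        raise ValueError("SNP positions must be integers (0-based)")
    if (df["pos"] < 0).any():
        raise ValueError("SNP positions must be non-negative (0-based)")
    for _, sub in df.groupby("chrom", sort=False):
        if np.any(np.diff(sub["pos"].to_numpy()) < 0):
            raise ValueError("SNP positions must be sorted within chromosome")
    maf = df["maf"].to_numpy(float)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    pv = df["pvalue"].to_numpy(float)
    ok = np.isnan(pv) | ((pv > 0) & (pv <= 1))
    if not ok.all():
        raise ValueError("pvalue must lie in (0, 1] when present")
    return df
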