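"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats
-------
- expression: long TSV with columns
  ``gene_id genotype_id replicate time_h count norm_value``
- genes: BED6 (``chrom start end name score strand``) or a gene TSV with an
  explicit ``tss`` column; coordinates 0-based half-open
- haplotypes: TSV ``pangene_id genotype_id haplotype_id``
- SNPs: TSV ``snp_id chrom pos maf pvalue`` plus optional ``gt_<ind>``
  dosage columns; or a minimal VCF (CHROM, POS, ID, REF, ALT, GT)
- promoters: FASTA (soft-masked bases uppercased on read)
- motifs: MEME minimal motif format

Malformed rows raise :class:`ParseError` naming the offending line.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import (
    GeneRecord,
    MotifPFM,
    validate_haplotype_table,
    validate_snp_table,
)

__all__ = [
    "ParseError",
    "read_expression", "write_expression",
    "read_genes_bed", "write_genes_bed",
    "read_genes_gff3",
    "read_genes_tsv", "write_genes_tsv",
    "read_haplotypes", "write_haplotypes",
    "read_snps", "write_snps", "read_vcf",
    "read_fasta", "write_fasta",
    "read_meme", "write_meme",
]

EXPRESSION_COLUMNS = ("gene_id", "genotype_id", "replicate", "time_h",
                      "count", "norm_value")


class ParseError(ValueError):
    """A malformed input row; the message names the file line."""


def _read_table(path, columns, dtypes) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing columns {missing}")
    for col, dtype in dtypes.items():
        raw = df[col]
        try:
            df[col] = raw.astype(dtype)
        except (ValueError, TypeError):
            bad = pd.to_numeric(raw, errors="coerce").isna() & raw.notna()
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2 if bad.any() else "?"
            raise ParseError(
                f"{path.name}, line {line}: column {col!r} value "
                f"{raw[bad.idxmax()] if bad.any() else '?'!r} is not {dtype}"
            ) from None
    return df


def read_expression(path) -> pd.DataFrame:
    df = _read_table(path, EXPRESSION_COLUMNS,
                     {"replicate": int, "time_h": float,
                      "count": float, "norm_value": float})
    if (df["norm_value"] < 0).any():
        bad = int((df["norm_value"] < 0).idxmax()) + 2
        raise ParseError(f"{Path(path).name}, line {bad}: negative abundance")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(EXPRESSION_COLUMNS))


def _gene_from_span(name, chrom, start, end, strand) -> GeneRecord:
    tss = start if strand == "+" else end
    return GeneRecord(gene_id=name, chrom=chrom, tss=tss, strand=strand,
                      gene_start=start, gene_end=end)


def read_genes_bed(path) -> list[GeneRecord]:
    """BED6 genes; the TSS is taken as the 5' end of the span."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{Path(path).name}, line {lineno}: expected 6 BED fields"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start, end = int(start), int(end)
            except ValueError:
                raise ParseError(
                    f"{Path(path).name}, line {lineno}: non-integer coordinate"
                ) from None
            if start < 0 or start >= end:
                raise ParseError(
                    f"{Path(path).name}, line {lineno}: interval "
                    f"[{start}, {end}) is not 0-based half-open"
                )
            try:
                genes.append(_gene_from_span(name, chrom, start, end, strand))
            except ValueError as exc:
                raise ParseError(
                    f"{Path(path).name}, line {lineno}: {exc}"
                ) from None
    return genes


def write_genes_bed(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.gene_start}\t{g.gene_end}\t"
                     f"{g.gene_id}\t0\t{g.strand}\n")


def read_genes_gff3(path, feature_type: str = "gene") -> list[GeneRecord]:
    """Minimal GFF3 gene reader (columns 1-5, 7 and the ID attribute).

    GFF3 coordinates are 1-based inclusive and are converted to the
    package's 0-based half-open convention on read.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"{Path(path).name}, line {lineno}: expected 9 GFF3 "
                    "columns")
            chrom, _src, ftype, start, end, _score, strand = fields[:7]
            if ftype != feature_type:
                continue
            try:
                start, end = int(start) - 1, int(end)
            except ValueError:
                raise ParseError(
                    f"{Path(path).name}, line {lineno}: non-integer "
                    "coordinate") from None
            match = re.search(r"(?:^|;)ID=([^;]+)", fields[8])
            if not match:
                raise ParseError(
                    f"{Path(path).name}, line {lineno}: missing ID "
                    "attribute")
            try:
                genes.append(_gene_from_span(match.group(1), chrom,
                                             start, end, strand))
            except ValueError as exc:
                raise ParseError(
                    f"{Path(path).name}, line {lineno}: {exc}") from None
    return genes


def read_genes_tsv(path) -> list[GeneRecord]:
    """Gene TSV with an explicit tss column (0-based, half-open span)."""
    df = _read_table(path,
                     ("gene_id", "chrom", "tss", "strand",
                      "gene_start", "gene_end"),
                     {"tss": int, "gene_start": int, "gene_end": int})
    genes = []
    for i, row in df.iterrows():
        try:
            genes.append(GeneRecord(row.gene_id, row.chrom, int(row.tss),
                                    row.strand, int(row.gene_start),
                                    int(row.gene_end)))
        except ValueError as exc:
            raise ParseError(f"{Path(path).name}, line {i + 2}: {exc}") from None
    return genes


def write_genes_tsv(genes, path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand, g.gene_start, g.gene_end)
         for g in genes],
        columns=["gene_id", "chrom", "tss", "strand",
                 "gene_start", "gene_end"],
    ).to_csv(path, sep="\t", index=False)


def read_haplotypes(path) -> pd.DataFrame:
    df = _read_table(path, ("pangene_id", "genotype_id", "haplotype_id"), {})
    return validate_haplotype_table(df)


def write_haplotypes(df: pd.DataFrame, path) -> None:
    validate_haplotype_table(df).to_csv(path, sep="\t", index=False)


def read_snps(path) -> pd.DataFrame:
    df = _read_table(path, ("snp_id", "chrom", "pos", "maf", "pvalue"),
                     {"pos": int, "maf": float, "pvalue": float})
    for col in df.columns:
        if col.startswith("gt_"):
            df[col] = df[col].astype(float)
    try:
        return validate_snp_table(df)
    except ValueError as exc:
        raise ParseError(f"{Path(path).name}: {exc}") from None


def write_snps(df: pd.DataFrame, path) -> None:
    validate_snp_table(df).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_vcf(path) -> pd.DataFrame:
    """Minimal VCF reader: CHROM, POS, ID, REF, ALT and GT dosages only.

    Returns a SNP table (pos converted to 0-based) with per-sample
    ``gt_<sample>`` dosage columns in {0, 1, 2, NaN} and MAF computed from
    the genotypes.  Association p-values are not carried by VCF and are NaN.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue  # biallelic sites only
            dosages = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    dosages.append(np.nan)
                else:
                    dosages.append(float(sum(gt)))
            arr = np.asarray(dosages)
            called = arr[~np.isnan(arr)]
            if called.size == 0:
                continue
            af = called.sum() / (2 * called.size)
            maf = min(af, 1 - af)
            if maf <= 0:
                continue  # monomorphic among called genotypes
            rows.append((rec.id or f"{rec.chrom}_{rec.pos}", rec.chrom,
                         rec.pos - 1, maf, np.nan, *dosages))
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "maf",
                                     "pvalue"] + [f"gt_{s}" for s in samples])
    df["pos"] = df["pos"].astype(int)
    return validate_snp_table(df)


def read_fasta(path) -> dict[str, str]:
    """FASTA as an ordered name -> sequence dict, uppercased on read."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not re.fullmatch(r"[ACGTN]*", seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ParseError(f"{Path(path).name}: record {rec.id} contains "
                             f"non-ACGTN characters {bad}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_meme(motifs: list[MotifPFM], path,
               alphabet: str = "ACGT") -> None:
    """MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n"
                 "strands: + -\n\n"
                 "Background letter frequencies\n"
                 "A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                     f"nsites= {max(m.n_sites, 1)} E= 0\n")
            for col in m.matrix.T:
                fh.write(" " + " ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[MotifPFM]:
    motifs = []
    name, width, nsites, rows = None, None, 0, []

    def flush():
        if name is not None:
            mat = np.asarray(rows, dtype=float).T
            # renormalize away printed-precision drift
            mat = mat / mat.sum(axis=0, keepdims=True)
            motifs.append(MotifPFM(mat, name=name, n_sites=nsites))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                name, width, nsites, rows = line.split()[1], None, 0, []
            elif line.startswith("letter-probability matrix"):
                m = re.search(r"w=\s*(\d+)", line)
                if not m:
                    raise ParseError(f"{Path(path).name}, line {lineno}: "
                                     "missing motif width")
                width = int(m.group(1))
                n = re.search(r"nsites=\s*(\d+)", line)
                nsites = int(n.group(1)) if n else 0
            elif name is not None and width is not None and line and \
                    not line.startswith(("MEME", "ALPHABET", "strands",
                                         "Background", "A 0.25")):
                vals = line.split()
                if len(vals) != 4:
                    raise ParseError(f"{Path(path).name}, line {lineno}: "
                                     "expected 4 probabilities")
                rows.append([float(v) for v in vals])
    flush()
    return motifs
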