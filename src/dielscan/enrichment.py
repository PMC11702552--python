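"""Permutation enrichment tests, Fst, and the night-day eQTL overlap test.

Candidate gene sets (e.g. DDR genes) are tested for

- GWAS signal: mean over candidates of the minimum association p-value in
  the gene span +/- 1 kb, against 1,000 equal-size samples from a null
  gene set (lower is enriched);
- overlap with adaptation-candidate SNPs in the same windows, against the
  same null sampling (higher is enriched);
- per-site Weir-Cockerham Fst between two phenotype-extreme groups, with
  the top 10,000 sites kept as putative adaptation variants;
- Fisher's combined test to aggregate p-values across selection scans.

The night-day response (nighttime minus daytime abundance) is scanned for
cis-eQTL within 5 kb of the focal gene; the overlap of cis-eQTL with GWAS
hits (p < 1e-5) is compared to 10,000 random SNP draws matched for MAF
and distance to the nearest gene.

All Monte-Carlo p-values use the (1 + more-extreme) / (1 + n) estimator
with ties counted as extreme; exhaustive enumeration (plain proportion)
replaces sampling when the number of distinct gene samples is small.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneRecord

logger = logging.getLogger(__name__)

__all__ = [
    "NullGeneSet",
    "EnrichmentResult",
    "FstResult",
    "gene_min_gwas_p",
    "gwas_enrichment",
    "adaptation_overlap_enrichment",
    "fisher_combined",
    "weir_cockerham_fst",
    "top_k_snps",
    "night_day_response",
    "cis_eqtl_scan",
    "matched_overlap_test",
    "build_null_sets",
]

NULL_SET_NAMES = ("all_genes", "transcribed", "cycling_ge2", "cycling_ge22")


@dataclass
class NullGeneSet:
    name: str
    gene_ids: frozenset

    def __post_init__(self):
        self.gene_ids = frozenset(self.gene_ids)
        if not self.gene_ids:
            raise ValueError(f"null gene set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    observed_stat: float
    null_stats: np.ndarray
    pvalue: float
    direction: str  # lower_is_enriched | higher_is_enriched
    null_set_name: str
    exhaustive: bool = False
    n_dropped: int = 0


@dataclass
class FstResult:
    snps: pd.DataFrame  # snp_id, a, b, c, fst (fst NaN when a+b+c == 0)


class _SnpIndex:
    """Sorted per-chromosome position index for window queries."""

    def __init__(self, snps: pd.DataFrame):
        self.snps = snps.reset_index(drop=True)
        self._by_chrom = {}
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            order = np.argsort(pos, kind="stable")
            self._by_chrom[chrom] = (pos[order], sub.index.to_numpy()[order])

    def window(self, chrom, start, end) -> np.ndarray:
        """Row indices of SNPs with start <= pos < end (half-open)."""
        if chrom not in self._by_chrom:
            return np.empty(0, dtype=int)
        pos, idx = self._by_chrom[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        return idx[lo:hi]


def _gene_window(gene: GeneRecord, flank: int):
    return gene.chrom, max(gene.gene_start - flank, 0), gene.gene_end + flank


def gene_min_gwas_p(gene: GeneRecord, snps: pd.DataFrame,
                    flank: int = 1000, index: _SnpIndex | None = None):
    """Minimum association p-value over SNPs in the gene span +/- flank.

    Returns NaN when the window holds no SNP with a p-value (the caller
    drops such genes from the mean and logs the count).
    """
    index = index or _SnpIndex(snps)
    chrom, start, end = _gene_window(gene, flank)
    rows = index.window(chrom, start, end)
    if len(rows) == 0:
        return float("nan")
    pv = index.snps.loc[rows, "pvalue"].to_numpy(float)
    pv = pv[~np.isnan(pv)]
    return float(pv.min()) if len(pv) else float("nan")


def _mean_min_p(gene_ids, min_p: pd.Series):
    vals = min_p.reindex(gene_ids).to_numpy(float)
    ok = ~np.isnan(vals)
    if not ok.any():
        return float("nan"), int((~ok).sum())
    return float(vals[ok].mean()), int((~ok).sum())


def _null_samples(null_ids: np.ndarray, k: int, n_samples: int,
                  rng: np.random.Generator,
                  exhaustive_limit: int) -> tuple[list, bool]:
    """Equal-size gene samples from the null set, exhaustive when small."""
    n = len(null_ids)
    if n < k:
        raise ValueError(
            f"null set ({n}) smaller than candidate set ({k})")
    n_comb = math.comb(n, k)
    if n_comb <= exhaustive_limit:
        return [np.asarray(c) for c in
                itertools.combinations(null_ids, k)], True
    samples = [rng.choice(null_ids, size=k, replace=False)
               for _ in range(n_samples)]
    return samples, False


def _permutation_pvalue(observed, null_stats, direction, exhaustive):
    null_stats = np.asarray(null_stats, float)
    if direction == "lower_is_enriched":
        extreme = null_stats <= observed + 1e-12
    else:
        extreme = null_stats >= observed - 1e-12
    if exhaustive:
        return float(np.mean(extreme))
    return (1 + int(extreme.sum())) / (1 + len(null_stats))


def gwas_enrichment(candidates, null_set: NullGeneSet,
                    snps: pd.DataFrame, genes: list[GeneRecord],
                    flank: int = 1000, n_samples: int = 1000,
                    seed=None, exhaustive_limit: int = 5000
                    ) -> EnrichmentResult:
    """Mean-min-p GWAS signal of a candidate gene set vs a null set.

    The observed statistic is the mean over candidates of the minimum
    GWAS p-value within each gene +/- ``flank``; lower means enriched.
    """
    rng = np.random.default_rng(seed)
    index = _SnpIndex(snps)
    by_id = {g.gene_id: g for g in genes}
    min_p = pd.Series({gid: gene_min_gwas_p(by_id[gid], snps, flank, index)
                       for gid in set(candidates) | set(null_set.gene_ids)})
    observed, dropped = _mean_min_p(list(candidates), min_p)
    if dropped:
        logger.info("gwas_enrichment: %d candidate genes without SNPs "
                    "dropped from the mean", dropped)
    samples, exhaustive = _null_samples(
        np.asarray(sorted(null_set.gene_ids)), len(list(candidates)),
        n_samples, rng, exhaustive_limit)
    null_stats = np.array([_mean_min_p(s, min_p)[0] for s in samples])
    p = _permutation_pvalue(observed, null_stats, "lower_is_enriched",
                            exhaustive)
    return EnrichmentResult(observed, null_stats, p, "lower_is_enriched",
                            null_set.name, exhaustive, dropped)


def _overlap_count(gene_ids, by_id, index, snp_rows_of_gene):
    rows = set()
    for gid in gene_ids:
        rows.update(snp_rows_of_gene[gid])
    return len(rows)


def adaptation_overlap_enrichment(candidates, adaptation_snps: pd.DataFrame,
                                  null_set: NullGeneSet,
                                  genes: list[GeneRecord],
                                  flank: int = 1000, n_samples: int = 1000,
                                  seed=None, exhaustive_limit: int = 5000
                                  ) -> EnrichmentResult:
    """Count of adaptation SNPs inside candidate gene windows vs null sets.

    Each adaptation SNP is counted once even if it falls in several
    windows; higher counts mean enriched.
    """
    rng = np.random.default_rng(seed)
    index = _SnpIndex(adaptation_snps)
    by_id = {g.gene_id: g for g in genes}
    all_ids = set(candidates) | set(null_set.gene_ids)
    snp_rows = {gid: index.window(*_gene_window(by_id[gid], flank))
                for gid in all_ids}
    observed = _overlap_count(list(candidates), by_id, index, snp_rows)
    samples, exhaustive = _null_samples(
        np.asarray(sorted(null_set.gene_ids)), len(list(candidates)),
        n_samples, rng, exhaustive_limit)
    null_stats = np.array([
        _overlap_count(s, by_id, index, snp_rows) for s in samples], float)
    p = _permutation_pvalue(observed, null_stats, "higher_is_enriched",
                            exhaustive)
    return EnrichmentResult(float(observed), null_stats, p,
                            "higher_is_enriched", null_set.name, exhaustive)


def fisher_combined(pvalues) -> float:
    """Fisher's method: -2 sum(ln p) ~ chi-square with 2k df."""
    pv = np.asarray(list(pvalues), dtype=float)
    if len(pv) == 0:
        raise ValueError("no p-values given")
    if np.any((pv <= 0) | (pv > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.sum(np.log(pv))
    return float(stats.chi2.sf(x, df=2 * len(pv)))


def weir_cockerham_fst(dosages_pop1, dosages_pop2,
                       snp_ids=None) -> FstResult:
    """Per-site Weir-Cockerham Fst between two diploid populations.

    Dosage matrices are (n_snps, n_individuals) with entries in
    {0, 1, 2, NaN}.  Returns the variance components a (among
    populations), b (among individuals within populations) and c (within
    individuals) and fst = a / (a + b + c); sites monomorphic across both
    populations (a + b + c == 0) get NaN.
    """
    d1 = np.atleast_2d(np.asarray(dosages_pop1, dtype=float))
    d2 = np.atleast_2d(np.asarray(dosages_pop2, dtype=float))
    if d1.shape[0] != d2.shape[0]:
        raise ValueError("populations must cover the same SNPs")
    r = 2.0

    def _pop_stats(d):
        called = ~np.isnan(d)
        n = called.sum(axis=1).astype(float)
        if np.any(n < 2):
            raise ValueError("need >= 2 non-missing genotypes per "
                             "population at every site")
        p = np.nansum(d, axis=1) / (2 * n)
        het = np.nansum(d == 1, axis=1) / n
        return n, p, het

    n1, p1, h1 = _pop_stats(d1)
    n2, p2, h2 = _pop_stats(d2)

    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4)
        / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r
        - h_bar * (2 * n_bar - 1) / (4 * n_bar))
    c = h_bar / 2

    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(denom != 0, a / denom, np.nan)
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(len(fst))]
    return FstResult(pd.DataFrame({
        "snp_id": snp_ids, "a": a, "b": b, "c": c, "fst": fst}))


def top_k_snps(fst_result: FstResult, snps: pd.DataFrame,
               k: int = 10000) -> pd.DataFrame:
    """The k highest-Fst SNPs; ties at the cutoff broken by genomic order."""
    scored = snps.merge(fst_result.snps[["snp_id", "fst"]], on="snp_id")
    scored = scored.dropna(subset=["fst"])
    if len(scored) == 0:
        raise ValueError("no scored SNPs")
    ordering = scored.sort_values(
        ["fst", "chrom", "pos"], ascending=[False, True, True],
        kind="stable")
    return ordering.head(k).sort_values(["chrom", "pos"]).reset_index(
        drop=True)


def night_day_response(night: pd.DataFrame, day: pd.DataFrame
                       ) -> pd.DataFrame:
    """Night minus day abundance per (gene, individual).

    Inputs are gene x individual tables; individuals missing either
    estimate get NaN.
    """
    genes = night.index.union(day.index)
    inds = night.columns.union(day.columns)
    return (night.reindex(index=genes, columns=inds)
            - day.reindex(index=genes, columns=inds))


def cis_eqtl_scan(response: pd.Series, snps: pd.DataFrame,
                  gene: GeneRecord, window: int = 5000,
                  min_individuals: int = 10) -> pd.DataFrame:
    """Additive-dosage regression of a per-individual response on cis SNPs.

    ``response`` is indexed by individual; genotype dosages come from the
    ``gt_<individual>`` columns of the SNP table.  Each SNP within the
    gene span +/- ``window`` is tested by simple linear regression with a
    two-sided t-test; missing genotypes are dropped pairwise and
    monomorphic SNPs are skipped.
    """
    index = _SnpIndex(snps)
    rows = index.window(*_gene_window(gene, window))
    gt_cols = {c[3:]: c for c in snps.columns if c.startswith("gt_")}
    inds = [i for i in response.index if i in gt_cols]
    out = []
    for row in rows:
        rec = index.snps.loc[row]
        dose = np.array([rec[gt_cols[i]] for i in inds], dtype=float)
        resp = response.loc[inds].to_numpy(float)
        ok = ~(np.isnan(dose) | np.isnan(resp))
        if ok.sum() < min_individuals:
            continue
        d, y = dose[ok], resp[ok]
        if np.all(d == d[0]):
            logger.info("cis_eqtl_scan: monomorphic SNP %s skipped",
                        rec["snp_id"])
            continue
        res = stats.linregress(d, y)
        out.append((rec["snp_id"], res.slope, res.stderr, res.pvalue,
                    int(ok.sum())))
    return pd.DataFrame(out, columns=["snp_id", "beta", "se", "pvalue", "n"])


def _distance_to_nearest_gene(snps: pd.DataFrame,
                              genes: list[GeneRecord]) -> np.ndarray:
    """bp distance from each SNP to the nearest gene span (0 if inside)."""
    dist = np.full(len(snps), np.inf)
    spans: dict[str, list] = {}
    for g in genes:
        spans.setdefault(g.chrom, []).append((g.gene_start, g.gene_end))
    starts_by_chrom = {}
    for chrom, ivs in spans.items():
        ivs.sort()
        starts_by_chrom[chrom] = (np.array([s for s, _ in ivs]),
                                  np.array([e for _, e in ivs]))
    pos_all = snps["pos"].to_numpy()
    for chrom, sub_idx in snps.groupby("chrom", sort=False).indices.items():
        if chrom not in starts_by_chrom:
            continue
        starts, ends = starts_by_chrom[chrom]
        pos = pos_all[sub_idx]
        j = np.searchsorted(starts, pos, side="right")
        d = np.full(len(pos), np.inf)
        # gene starting at or after the SNP
        has_next = j < len(starts)
        d[has_next] = starts[j[has_next]] - pos[has_next]
        # genes starting before the SNP (span may contain it)
        for back in range(1, len(starts) + 1):
            jj = j - back
            ok = jj >= 0
            if not ok.any():
                break
            prev_end = ends[jj[ok]]
            gap = np.maximum(pos[ok] - (prev_end - 1), 0)
            inside = (pos[ok] >= starts[jj[ok]]) & (pos[ok] < prev_end)
            gap = np.where(inside, 0, gap)
            d[ok] = np.minimum(d[ok], gap)
            if back >= 2:  # spans are short relative to spacing; 2 suffices
                break
        dist[sub_idx] = d
    return dist


DEFAULT_DISTANCE_EDGES = (0, 500, 1000, 2500, 5000)


def _stratify(snps: pd.DataFrame, genes: list[GeneRecord],
              n_maf_bins: int = 10,
              distance_edges=DEFAULT_DISTANCE_EDGES):
    """(MAF decile, distance bin) stratum label per SNP."""
    maf = snps["maf"].to_numpy(float)
    quantiles = np.quantile(maf, np.linspace(0, 1, n_maf_bins + 1))
    quantiles[0], quantiles[-1] = -np.inf, np.inf
    maf_bin = np.clip(np.searchsorted(quantiles, maf, side="right") - 1,
                      0, n_maf_bins - 1)
    dist = _distance_to_nearest_gene(snps, genes)
    edges = np.asarray(distance_edges, float)
    # bins: {0}, (0,500], (500,1000], (1000,2500], (2500,5000], >5000
    dist_bin = np.searchsorted(edges, dist, side="left")
    dist_bin[dist == 0] = 0
    return maf_bin, dist_bin, n_maf_bins


def matched_overlap_test(eqtl_snp_ids, all_snps: pd.DataFrame,
                         genes: list[GeneRecord],
                         gwas_hit_threshold: float = 1e-5,
                         n_draws: int = 10000, seed=None,
                         n_maf_bins: int = 10,
                         distance_edges=DEFAULT_DISTANCE_EDGES
                         ) -> EnrichmentResult:
    """GWAS-hit overlap of eQTL SNPs vs matched random SNP draws.

    For every eQTL SNP each draw samples one SNP from the same
    (MAF-decile x distance-to-nearest-gene) stratum; the null statistic
    is the number of sampled SNPs that are GWAS hits (p < threshold).
    An empty stratum is widened to the neighboring MAF bins with a
    warning.
    """
    rng = np.random.default_rng(seed)
    snps = all_snps.reset_index(drop=True)
    maf_bin, dist_bin, n_maf = _stratify(snps, genes, n_maf_bins,
                                         distance_edges)
    is_hit = (snps["pvalue"].to_numpy(float) < gwas_hit_threshold)
    is_hit = np.where(np.isnan(snps["pvalue"].to_numpy(float)), False,
                      is_hit)
    id_to_row = {s: i for i, s in enumerate(snps["snp_id"])}
    eqtl_rows = [id_to_row[s] for s in eqtl_snp_ids]
    observed = float(np.sum(is_hit[eqtl_rows]))

    members: dict[tuple, np.ndarray] = {}
    key_arr = list(zip(maf_bin, dist_bin))
    for i, key in enumerate(key_arr):
        members.setdefault(key, []).append(i)
    members = {k: np.asarray(v) for k, v in members.items()}

    null_counts = np.zeros(n_draws)
    for row in eqtl_rows:
        key = (maf_bin[row], dist_bin[row])
        pool = members.get(key, np.empty(0, int))
        pool = pool[pool != row]  # draw matched SNPs other than itself
        width = 0
        while len(pool) == 0 and width < n_maf:
            width += 1
            warnings.warn(
                f"empty matching stratum {key}; widening MAF bin by "
                f"+/-{width}", stacklevel=2)
            pools = [members.get((key[0] + off, key[1]), np.empty(0, int))
                     for off in (-width, width)]
            pool = np.concatenate(pools)
        if len(pool) == 0:
            raise ValueError(f"no SNPs available to match stratum {key}")
        draws = pool[rng.integers(0, len(pool), size=n_draws)]
        null_counts += is_hit[draws]

    p = _permutation_pvalue(observed, null_counts, "higher_is_enriched",
                            exhaustive=False)
    return EnrichmentResult(observed, null_counts, p, "higher_is_enriched",
                            "matched_snps")


def build_null_sets(rhythm: pd.DataFrame, expr: pd.DataFrame,
                    all_gene_ids=None, cycling_alpha: float = 0.01,
                    transcribed_floor: float = 5.0,
                    nearly_all: int = 22) -> dict[str, NullGeneSet]:
    """The four standard null gene sets from a rhythmicity scan.

    all_genes: every annotated gene; transcribed: genes whose maximum
    normalized abundance in any inbred exceeds ``transcribed_floor``;
    cycling_ge2 / cycling_ge22: genes cycling (p < alpha) in at least 2 /
    at least ``nearly_all`` inbreds.  Candidate genes are not excluded.
    """
    if all_gene_ids is None:
        all_gene_ids = sorted(set(expr["gene_id"]))
    max_expr = expr.groupby("gene_id")["norm_value"].max()
    transcribed = set(max_expr.index[max_expr > transcribed_floor])
    cycl = rhythm[rhythm["pvalue"] < cycling_alpha]
    counts = cycl.groupby("gene_id")["genotype_id"].nunique()
    ge2 = set(counts.index[counts >= 2])
    ge22 = set(counts.index[counts >= nearly_all])
    sets = {}
    for name, ids in (("all_genes", set(all_gene_ids)),
                      ("transcribed", transcribed),
                      ("cycling_ge2", ge2),
                      ("cycling_ge22", ge22)):
        if ids:
            sets[name] = NullGeneSet(name, frozenset(ids))
    return sets
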