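"""Differential Diel Regulation: promoter-haplotype association testing.

A pan-gene is a DDR candidate when the diel range of its expression
(max - min over the 24 h course, per inbred) co-segregates with promoter
haplotype.  Association is measured by the Kruskal-Wallis H statistic and
a label-permutation null (10,000 permutations by default; exhaustive
enumeration when the number of distinct label assignments is small).
Candidacy additionally requires at least six cycling inbreds
(rhythmicity p < 0.01) and at least six inbreds with baseline abundance
above 50 — "baseline" taken as the mean normalized abundance across the
time course.

Confirmation in the growth-chamber design uses pairwise amplitude-
difference LR tests between haplotype groups, keeping the smallest
p-value when three haplotypes are present (no multiplicity correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import TimeSeriesExpression
from .rhythm import lr_diff_amplitude

__all__ = [
    "DdrTestResult",
    "diel_range",
    "kw_statistic",
    "kw_permutation_p",
    "identify_ddr",
    "ddr_scan",
    "confirm_ddr",
    "confirm_ddr_scan",
]

UNTESTED = "untested"


@dataclass
class DdrTestResult:
    pangene_id: str
    kw_H: float
    perm_pvalue: float
    n_cycling_inbreds: int
    n_expressed_inbreds: int
    is_candidate: bool


def diel_range(series: TimeSeriesExpression) -> float:
    """Max minus min abundance over the course, replicates averaged first."""
    if series.n_obs == 0:
        raise ValueError("empty series")
    _, means = series.timepoint_means()
    return float(means.max() - means.min())


def _check_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise ValueError("values and groups must be equal-length 1-D arrays")
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    return values, codes, len(labels)


def kw_statistic(values, groups) -> float:
    """Kruskal-Wallis H with tie correction; 0 when all values are equal."""
    values, codes, k = _check_groups(values, groups)
    if np.all(values == values[0]):
        return 0.0
    samples = [values[codes == j] for j in range(k)]
    return float(stats.kruskal(*samples).statistic)


def _h_from_rank_sums(rank_sums, group_sizes, n, tie_factor):
    """Vectorized tie-corrected H from per-group rank sums."""
    h = 12.0 / (n * (n + 1)) * np.sum(rank_sums ** 2 / group_sizes,
                                      axis=-1) - 3 * (n + 1)
    return h / tie_factor


def _tie_factor(values) -> float:
    _, counts = np.unique(values, return_counts=True)
    n = len(values)
    return 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)


def _n_distinct_assignments(group_sizes) -> int:
    n = int(np.sum(group_sizes))
    total = math.factorial(n)
    for s in group_sizes:
        total //= math.factorial(int(s))
    return total


def kw_permutation_p(values, groups, n_perm: int = 10000,
                     seed=None, exhaustive_limit: int = 200) -> float:
    """Label-permutation p-value of the Kruskal-Wallis statistic.

    When the number of distinct label assignments is at most
    ``exhaustive_limit`` the null is enumerated exactly and the p-value is
    the plain proportion of assignments with H at least the observed value
    (the observed assignment is one of them).  Otherwise ``n_perm``
    random permutations are drawn and the (1 + more-extreme)/(1 + n_perm)
    estimator is used, so the p-value never falls below 1/(n_perm + 1).
    """
    values, codes, k = _check_groups(values, groups)
    n = len(values)
    h_obs = kw_statistic(values, codes)
    if h_obs == 0.0:
        return 1.0
    tie = _tie_factor(values)
    ranks = stats.rankdata(values)
    sizes = np.bincount(codes, minlength=k).astype(float)
    onehot = np.eye(k)[codes]  # (n, k)

    n_assign = _n_distinct_assignments(sizes)
    if n_assign <= exhaustive_limit:
        from sympy.utilities.iterables import multiset_permutations

        h_all = []
        for perm in multiset_permutations(list(codes)):
            oh = np.eye(k)[np.asarray(perm)]
            h_all.append(_h_from_rank_sums(ranks @ oh, sizes, n, tie))
        h_all = np.asarray(h_all)
        return float(np.mean(h_all >= h_obs - 1e-12))

    rng = np.random.default_rng(seed)
    perm_ranks = rng.permuted(
        np.broadcast_to(ranks, (n_perm, n)).copy(), axis=1)
    rank_sums = perm_ranks @ onehot  # (n_perm, k)
    h_perm = _h_from_rank_sums(rank_sums, sizes, n, tie)
    more = int(np.sum(h_perm >= h_obs - 1e-12))
    return (1 + more) / (1 + n_perm)


def identify_ddr(pangene_id: str,
                 responses: pd.Series,
                 haplotypes: pd.Series,
                 cycling_pvalues: pd.Series,
                 baselines: pd.Series,
                 min_cycling: int = 6,
                 cycling_alpha: float = 0.01,
                 min_expressed: int = 6,
                 expr_floor: float = 50.0,
                 kw_alpha: float = 0.05,
                 n_perm: int = 10000,
                 seed=None) -> DdrTestResult:
    """Field-design DDR test of one pan-gene.

    All four series are indexed by inbred (genotype_id): ``responses`` is
    the diel range, ``haplotypes`` the promoter haplotype ID,
    ``cycling_pvalues`` the single-inbred rhythmicity p-values and
    ``baselines`` the mean normalized abundance.  Inbreds missing a
    haplotype or response are excluded from the KW test; the cycling and
    baseline filters count over all inbreds with data.
    """
    n_cycling = int((cycling_pvalues.dropna() < cycling_alpha).sum())
    n_expressed = int((baselines.dropna() > expr_floor).sum())

    common = responses.dropna().index.intersection(haplotypes.dropna().index)
    vals = responses.loc[common].to_numpy(float)
    haps = haplotypes.loc[common].to_numpy()
    if len(common) and len(np.unique(haps)) >= 2:
        h = kw_statistic(vals, haps)
        p = kw_permutation_p(vals, haps, n_perm=n_perm, seed=seed)
    else:
        h, p = float("nan"), float("nan")

    is_candidate = bool(
        np.isfinite(p) and p < kw_alpha
        and n_cycling >= min_cycling
        and n_expressed >= min_expressed
    )
    return DdrTestResult(pangene_id=pangene_id, kw_H=h, perm_pvalue=p,
                         n_cycling_inbreds=n_cycling,
                         n_expressed_inbreds=n_expressed,
                         is_candidate=is_candidate)


def _per_inbred_tables(expr: pd.DataFrame):
    """Diel range and baseline per (gene, genotype) from a long table."""
    def _range(sub):
        by_t = sub.groupby("time_h")["norm_value"].mean()
        return by_t.max() - by_t.min()

    grouped = expr.groupby(["gene_id", "genotype_id"])
    ranges = grouped.apply(_range, include_groups=False)
    baselines = grouped["norm_value"].mean()
    return ranges, baselines


def ddr_scan(expr: pd.DataFrame,
             haplotypes: pd.DataFrame,
             rhythm: pd.DataFrame,
             pangene_members: dict[str, dict[str, str]] | None = None,
             seed=None,
             n_perm: int = 10000,
             **thresholds) -> pd.DataFrame:
    """Run :func:`identify_ddr` over every pan-gene in a haplotype table.

    ``pangene_members`` maps pangene_id -> {genotype_id: gene_id}; when
    omitted, gene_id is assumed to equal pangene_id in the expression and
    rhythm tables.
    """
    ranges, baselines = _per_inbred_tables(expr)
    rhythm_p = rhythm.set_index(["gene_id", "genotype_id"])["pvalue"]
    ss = np.random.SeedSequence(seed)

    rows = []
    pangene_ids = haplotypes["pangene_id"].unique()
    child_seeds = ss.spawn(len(pangene_ids))
    for pg, child in zip(pangene_ids, child_seeds):
        hap = haplotypes[haplotypes["pangene_id"] == pg].set_index(
            "genotype_id")["haplotype_id"]
        members = (pangene_members or {}).get(pg)
        if members is None:
            members = {g: pg for g in hap.index}

        def _collect(table):
            out = {}
            for geno, gid in members.items():
                if (gid, geno) in table.index:
                    out[geno] = table.loc[(gid, geno)]
            return pd.Series(out, dtype=float)

        res = identify_ddr(
            pg,
            responses=_collect(ranges),
            haplotypes=hap,
            cycling_pvalues=_collect(rhythm_p),
            baselines=_collect(baselines),
            n_perm=n_perm,
            seed=child,
            **thresholds,
        )
        rows.append((res.pangene_id, res.kw_H, res.perm_pvalue,
                     res.n_cycling_inbreds, res.n_expressed_inbreds,
                     res.is_candidate))
    return pd.DataFrame(rows, columns=[
        "pangene_id", "kw_H", "perm_pvalue", "n_cycling_inbreds",
        "n_expressed_inbreds", "is_candidate"])


def confirm_ddr(series_by_genotype: dict[str, TimeSeriesExpression],
                haplotype_by_genotype: dict[str, str],
                period: float = 24.0):
    """Growth-chamber confirmation of one gene.

    Returns ``(status, pvalue)``: genotypes sharing a single haplotype (or
    no usable expression) give ``("untested", nan)``; two haplotype groups
    give the amplitude-difference LR p-value; three give the minimum of
    the three pairwise p-values (kept without multiplicity correction).
    """
    genos = [g for g in haplotype_by_genotype if g in series_by_genotype]
    if not genos:
        return UNTESTED, float("nan")
    by_hap: dict[str, list] = {}
    for g in genos:
        by_hap.setdefault(haplotype_by_genotype[g], []).append(
            series_by_genotype[g])
    haps = sorted(by_hap)
    if len(haps) < 2:
        return UNTESTED, float("nan")
    pvals = []
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            test = lr_diff_amplitude(by_hap[haps[i]], by_hap[haps[j]],
                                     period=period)
            pvals.append(test.pvalue)
    return "tested", float(min(pvals))


def confirm_ddr_scan(chamber_expr: pd.DataFrame,
                     haplotypes: pd.DataFrame,
                     candidates: list[str],
                     pangene_members: dict[str, dict[str, str]] | None = None,
                     alpha: float = 0.01,
                     period: float = 24.0) -> pd.DataFrame:
    """Confirm field DDR candidates in the growth-chamber design."""
    rows = []
    for pg in candidates:
        hap = haplotypes[haplotypes["pangene_id"] == pg].set_index(
            "genotype_id")["haplotype_id"].to_dict()
        members = (pangene_members or {}).get(pg)
        if members is None:
            members = {g: pg for g in hap}
        series = {}
        for geno, gid in members.items():
            sub = chamber_expr[(chamber_expr["gene_id"] == gid)
                               & (chamber_expr["genotype_id"] == geno)]
            sub = sub.sort_values(["replicate", "time_h"])
            if len(sub) >= 4:
                series[geno] = TimeSeriesExpression(
                    gene_id=gid, genotype_id=geno,
                    times=sub["time_h"].to_numpy(float),
                    values=sub["norm_value"].to_numpy(float),
                    replicate=sub["replicate"].to_numpy(int))
        status, p = confirm_ddr(series, hap, period=period)
        confirmed = status == "tested" and p < alpha
        rows.append((pg, status, p, confirmed))
    return pd.DataFrame(rows, columns=["pangene_id", "status", "pvalue",
                                       "confirmed"])
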