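"""Permutation enrichment, Fst, Fisher's method and the eQTL overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dielscan.datamodel import GeneRecord
from dielscan.enrichment import (
    NullGeneSet,
    adaptation_overlap_enrichment,
    cis_eqtl_scan,
    fisher_combined,
    gene_min_gwas_p,
    gwas_enrichment,
    matched_overlap_test,
    night_day_response,
    top_k_snps,
    weir_cockerham_fst,
)


def make_genes(n, spacing=10000, length=2000, chrom="chr1"):
    return [GeneRecord(f"g{i}", chrom, 1000 + i * spacing, "+",
                       1000 + i * spacing, 1000 + i * spacing + length)
            for i in range(n)]


def make_snps(positions, pvalues, chrom="chr1", maf=0.2):
    positions = np.asarray(positions)
    order = np.argsort(positions)
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in order],
        "chrom": chrom,
        "pos": positions[order].astype(int),
        "maf": maf,
        "pvalue": np.asarray(pvalues)[order],
    })


class TestGeneMinP:
    def test_minimum_in_window(self):
        gene = make_genes(1)[0]  # span [1000, 3000)
        snps = make_snps([1500, 2000, 2500], [0.3, 0.001, 0.8])
        assert gene_min_gwas_p(gene, snps) == pytest.approx(0.001)

    def test_no_snps_is_missing(self):
        gene = make_genes(1)[0]
        snps = make_snps([900000], [0.5])
        assert np.isnan(gene_min_gwas_p(gene, snps))

    def test_flank_boundary_half_open(self):
        gene = make_genes(1)[0]  # span [1000, 3000), window [0, 4000)
        at_edge = make_snps([4000], [0.001])
        assert np.isnan(gene_min_gwas_p(gene, at_edge))
        inside = make_snps([3999], [0.001])
        assert gene_min_gwas_p(gene, inside) == pytest.approx(0.001)


class TestGwasEnrichment:
    def test_extreme_separation_hits_floor(self, rng):
        genes = make_genes(20)
        pos, pv = [], []
        for i, g in enumerate(genes):
            pos.append(g.gene_start + 100)
            pv.append(1e-9 if i < 5 else rng.uniform(0.4, 1.0))
        snps = make_snps(pos, pv)
        null = NullGeneSet("all_genes", {g.gene_id for g in genes})
        res = gwas_enrichment([f"g{i}" for i in range(5)], null, snps,
                              genes, n_samples=200, seed=0,
                              exhaustive_limit=0)
        assert res.pvalue == pytest.approx(1 / 201)

    def test_exhaustive_matches_enumeration(self, rng):
        genes = make_genes(5)
        snps = make_snps([g.gene_start + 50 for g in genes],
                         rng.uniform(0.01, 1.0, 5))
        null = NullGeneSet("all_genes", {g.gene_id for g in genes})
        cands = ["g0", "g1", "g2"]
        res = gwas_enrichment(cands, null, snps, genes, seed=0)
        assert res.exhaustive
        min_p = {g.gene_id: gene_min_gwas_p(g, snps) for g in genes}
        obs = np.mean([min_p[c] for c in cands])
        stats_all = [np.mean([min_p[g] for g in combo]) for combo in
                     itertools.combinations(sorted(null.gene_ids), 3)]
        expected = np.mean([s <= obs + 1e-12 for s in stats_all])
        assert res.pvalue == pytest.approx(expected)

    def test_null_calibration_uniform(self):
        """Candidates drawn from the null set give uniform p-values."""
        rng = np.random.default_rng(0)
        genes = make_genes(60)
        snps = make_snps([g.gene_start + 10 for g in genes],
                         rng.uniform(0, 1, 60))
        null = NullGeneSet("all_genes", {g.gene_id for g in genes})
        pvals = []
        for _ in range(100):
            cands = rng.choice(sorted(null.gene_ids), 10, replace=False)
            res = gwas_enrichment(cands, null, snps, genes,
                                  n_samples=200,
                                  seed=rng.integers(2 ** 31),
                                  exhaustive_limit=0)
            pvals.append(res.pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_null_smaller_than_candidates_rejected(self):
        genes = make_genes(3)
        snps = make_snps([g.gene_start for g in genes], [0.5] * 3)
        null = NullGeneSet("all_genes", {"g0"})
        with pytest.raises(ValueError, match="smaller"):
            gwas_enrichment(["g0", "g1"], null, snps, genes)


class TestAdaptationOverlap:
    def test_no_adaptation_snps_gives_p_one(self):
        genes = make_genes(10)
        empty = make_snps([], [])
        null = NullGeneSet("all_genes", {g.gene_id for g in genes})
        res = adaptation_overlap_enrichment(
            ["g0", "g1"], empty, null, genes, n_samples=100, seed=0,
            exhaustive_limit=0)
        assert res.observed_stat == 0
        assert res.pvalue == 1.0

    def test_perfect_overlap_hits_floor(self):
        genes = make_genes(10)
        adapt = make_snps([genes[0].gene_start + 5,
                           genes[1].gene_start + 5], [0.5, 0.5])
        null = NullGeneSet("all_genes", {g.gene_id for g in genes})
        res = adaptation_overlap_enrichment(
            ["g0", "g1"], adapt, null, genes, n_samples=400, seed=0,
            exhaustive_limit=0)
        assert res.pvalue < 0.02

    def test_exhaustive_matches_enumeration(self):
        genes = make_genes(5)
        adapt = make_snps([genes[0].gene_start + 5,
                           genes[2].gene_start + 5,
                           genes[2].gene_start + 50], [0.5] * 3)
        null = NullGeneSet("all_genes", {g.gene_id for g in genes})
        cands = ["g0", "g2"]
        res = adaptation_overlap_enrichment(cands, adapt, null, genes,
                                            seed=0)
        assert res.exhaustive

        def count(ids):
            hits = set()
            for g in genes:
                if g.gene_id not in ids:
                    continue
                for _, s in adapt.iterrows():
                    if g.gene_start - 1000 <= s.pos < g.gene_end + 1000:
                        hits.add(s.snp_id)
            return len(hits)

        obs = count(cands)
        vals = [count(set(c)) for c in
                itertools.combinations(sorted(null.gene_ids), 2)]
        expected = np.mean([v >= obs for v in vals])
        assert res.pvalue == pytest.approx(expected)


class TestFisherCombined:
    def test_identity_at_k1(self):
        assert fisher_combined([0.5]) == pytest.approx(0.5)
        assert fisher_combined([0.123]) == pytest.approx(0.123)

    def test_all_ones(self):
        assert fisher_combined([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_chi_square_oracle(self):
        x = -2 * (np.log(0.05) + np.log(0.05))
        assert x == pytest.approx(11.983, abs=1e-3)
        assert fisher_combined([0.05, 0.05]) == pytest.approx(
            stats.chi2.sf(x, 4))

    def test_agrees_with_scipy(self, rng):
        pv = rng.uniform(0.001, 1, 6)
        expected = stats.combine_pvalues(pv, method="fisher").pvalue
        assert fisher_combined(pv) == pytest.approx(expected)

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            fisher_combined([0.0, 0.5])


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        d1 = np.zeros((2, 30))
        d2 = np.full((2, 30), 2.0)
        res = weir_cockerham_fst(d1, d2)
        np.testing.assert_allclose(res.snps["fst"], 1.0)

    def test_identical_populations_not_positive(self):
        d = np.array([[0, 0, 1, 1, 2, 2]], dtype=float)
        res = weir_cockerham_fst(d, d.copy())
        assert res.snps["fst"].iloc[0] <= 1e-12

    def test_hand_computed_case(self):
        # pop1: 0/0, 0/1  -> p=0.25, het=0.5 ; pop2: 1/1, 0/1 -> p=0.75
        # variance components worked by hand: a=1/16, b=0, c=1/4
        res = weir_cockerham_fst([[0, 1]], [[2, 1]])
        row = res.snps.iloc[0]
        assert row["a"] == pytest.approx(0.0625)
        assert row["b"] == pytest.approx(0.0)
        assert row["c"] == pytest.approx(0.25)
        assert row["fst"] == pytest.approx(0.2)

    def test_monomorphic_is_missing(self):
        res = weir_cockerham_fst([[0, 0, 0]], [[0, 0, 0]])
        assert np.isnan(res.snps["fst"].iloc[0])

    def test_panmixia_mean_near_zero(self):
        rng = np.random.default_rng(9)
        n_snp, n_ind = 400, 30
        p = rng.uniform(0.1, 0.5, n_snp)
        draw = lambda: (rng.random((n_snp, n_ind)) < p[:, None]).astype(
            float) + (rng.random((n_snp, n_ind)) < p[:, None])
        res = weir_cockerham_fst(draw(), draw())
        fst = res.snps["fst"].dropna()
        assert abs(fst.mean()) < 3 * fst.std() / np.sqrt(len(fst))


class TestTopK:
    def _fst_table(self, ids, scores, positions):
        from dielscan.enrichment import FstResult

        res = FstResult(pd.DataFrame({
            "snp_id": ids, "a": 0.0, "b": 0.0, "c": 0.0, "fst": scores}))
        snps = pd.DataFrame({
            "snp_id": ids, "chrom": "chr1", "pos": positions,
            "maf": 0.2, "pvalue": 0.5}).sort_values(
                "pos").reset_index(drop=True)
        return res, snps

    def test_fewer_than_k_keeps_all(self):
        res, snps = self._fst_table(list("abcde"), [0.5, 0.4, 0.3, 0.2,
                                                    0.1],
                                    [10, 20, 30, 40, 50])
        assert len(top_k_snps(res, snps, k=10)) == 5

    def test_top_k_by_score(self):
        res, snps = self._fst_table(list("abcde"),
                                    [0.1, 0.9, 0.5, 0.7, 0.2],
                                    [10, 20, 30, 40, 50])
        top = top_k_snps(res, snps, k=2)
        assert set(top["snp_id"]) == {"b", "d"}

    def test_tie_broken_by_genomic_order(self):
        res, snps = self._fst_table(list("abc"), [0.5, 0.5, 0.5],
                                    [30, 10, 20])
        top = top_k_snps(res, snps, k=2)
        # positions: a@30, b@10, c@20 -> earlier positions kept
        assert set(top["snp_id"]) == {"b", "c"}


class TestNightDay:
    def test_difference_and_missing(self):
        night = pd.DataFrame({"i1": [10.0], "i2": [4.0]}, index=["g"])
        day = pd.DataFrame({"i1": [4.0], "i3": [1.0]}, index=["g"])
        resp = night_day_response(night, day)
        assert resp.loc["g", "i1"] == pytest.approx(6.0)
        assert np.isnan(resp.loc["g", "i2"])
        assert np.isnan(resp.loc["g", "i3"])


class TestCisEqtl:
    def _snps_with_genotypes(self, rng, n_ind=20, pos=1500):
        dose = rng.integers(0, 3, n_ind).astype(float)
        df = make_snps([pos], [0.5])
        for j, d in enumerate(dose):
            df[f"gt_i{j}"] = d
        return df, dose

    def test_perfect_signal(self, rng):
        gene = make_genes(1)[0]
        snps, dose = self._snps_with_genotypes(rng)
        resp = pd.Series(2.0 * dose, index=[f"i{j}" for j in range(20)])
        out = cis_eqtl_scan(resp, snps, gene)
        assert out["pvalue"].iloc[0] < 1e-10

    def test_matches_closed_form_ols(self, rng):
        gene = make_genes(1)[0]
        snps, dose = self._snps_with_genotypes(rng)
        resp_vals = 0.5 * dose + rng.normal(0, 1, 20)
        resp = pd.Series(resp_vals, index=[f"i{j}" for j in range(20)])
        out = cis_eqtl_scan(resp, snps, gene)
        x, y = dose, resp_vals
        beta = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        resid = y - y.mean() - beta * (x - x.mean())
        se = np.sqrt(resid @ resid / 18 / ((x - x.mean()) @ (x - x.mean())))
        tstat = beta / se
        p = 2 * stats.t.sf(abs(tstat), 18)
        assert out["beta"].iloc[0] == pytest.approx(beta, abs=1e-9)
        assert out["pvalue"].iloc[0] == pytest.approx(p, abs=1e-9)

    def test_window_restriction_and_monomorphic_skip(self, rng):
        gene = make_genes(1)[0]
        inside, dose = self._snps_with_genotypes(rng, pos=1500)
        outside, _ = self._snps_with_genotypes(rng, pos=900000)
        mono = inside.copy()
        mono["pos"] = 1600
        mono["snp_id"] = "mono"
        for c in mono.columns:
            if c.startswith("gt_"):
                mono[c] = 1.0
        snps = pd.concat([inside, mono, outside]).sort_values(
            "pos").reset_index(drop=True)
        resp = pd.Series(rng.normal(0, 1, 20),
                         index=[f"i{j}" for j in range(20)])
        out = cis_eqtl_scan(resp, snps, gene)
        assert out["snp_id"].tolist() == [inside["snp_id"].iloc[0]]

    def test_null_calibration(self):
        rng = np.random.default_rng(13)
        gene = make_genes(1)[0]
        n_rej, n_rep = 0, 800
        for _ in range(n_rep):
            snps, dose = self._snps_with_genotypes(rng)
            resp = pd.Series(rng.normal(0, 1, 20),
                             index=[f"i{j}" for j in range(20)])
            out = cis_eqtl_scan(resp, snps, gene)
            if len(out):
                n_rej += out["pvalue"].iloc[0] < 0.05
        rate = n_rej / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep) + 0.005


class TestMatchedOverlap:
    def _setup(self, rng, n_snps=600):
        genes = make_genes(10)
        pos = np.sort(rng.choice(120000, n_snps, replace=False))
        snps = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(n_snps)],
            "chrom": "chr1", "pos": pos.astype(int),
            "maf": rng.uniform(0.05, 0.5, n_snps),
            "pvalue": rng.uniform(0, 1, n_snps)})
        return genes, snps

    def test_all_hits_hits_floor(self, rng):
        genes, snps = self._setup(rng)
        snps.loc[:9, "pvalue"] = 1e-9
        snps.loc[10:, "pvalue"] = 0.5
        eqtl = snps["snp_id"].iloc[:10].tolist()
        # make the chosen SNPs alone in their strata impossible: use
        # one shared stratum by uniform maf/distance is unlikely, so
        # just check the p-value is small
        res = matched_overlap_test(eqtl, snps, genes, n_draws=300,
                                   seed=0)
        assert res.observed_stat == 10
        assert res.pvalue < 0.05

    def test_zero_observed_gives_p_one(self, rng):
        genes, snps = self._setup(rng)
        snps["pvalue"] = 0.5
        res = matched_overlap_test(snps["snp_id"].iloc[:5].tolist(),
                                   snps, genes, n_draws=100, seed=0)
        assert res.observed_stat == 0
        assert res.pvalue == 1.0

    def test_matched_null_calibration(self):
        """eQTL SNPs drawn from their own strata give uniform p.

        The hit threshold is raised so hits are common enough for the
        overlap statistic to have fine granularity.
        """
        rng = np.random.default_rng(3)
        genes, snps = self._setup(rng, n_snps=800)
        snps["pvalue"] = rng.uniform(0, 1, len(snps))
        pvals = []
        for _ in range(100):
            eqtl = rng.choice(snps["snp_id"], 40, replace=False)
            res = matched_overlap_test(list(eqtl), snps, genes,
                                       gwas_hit_threshold=0.3,
                                       n_draws=400,
                                       seed=rng.integers(2 ** 31))
            pvals.append(res.pvalue)
        pvals = np.asarray(pvals)
        # approximately uniform: central mean and honest tail mass
        assert abs(pvals.mean() - 0.5) < 0.1
        assert np.mean(pvals < 0.1) < 0.2
        assert np.mean(pvals < 0.5) == pytest.approx(0.5, abs=0.17)

    def test_empty_stratum_widens_with_warning(self, rng):
        genes = make_genes(10)
        # 50 SNPs far from any gene (one distance bin) with distinct MAF
        # deciles at n_maf_bins=50: each stratum holds one SNP, so the
        # focal SNP has no matching partner and the bin must widen
        snps = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(50)],
            "chrom": "chr1",
            "pos": np.arange(400000, 400500, 10),
            "maf": np.linspace(0.05, 0.5, 50),
            "pvalue": 0.5})
        with pytest.warns(UserWarning, match="widening"):
            matched_overlap_test(["s0"], snps, genes, n_draws=50,
                                 seed=0, n_maf_bins=50)
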