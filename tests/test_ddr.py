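"""Kruskal-Wallis permutation DDR detection and chamber confirmation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dielscan as ds
from dielscan.datamodel import TimeSeriesExpression
from dielscan.ddr import (
    confirm_ddr,
    diel_range,
    identify_ddr,
    kw_permutation_p,
    kw_statistic,
)


def exhaustive_kw_p(values, groups):
    """Independent enumeration oracle over all distinct label
    assignments."""
    from itertools import permutations

    values = np.asarray(values, float)
    h_obs = kw_statistic(values, groups)
    seen = set()
    hits = total = 0
    for perm in set(permutations(groups)):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        hits += kw_statistic(values, list(perm)) >= h_obs - 1e-12
    return hits / total


class TestDielRange:
    def test_constant_is_zero(self):
        s = TimeSeriesExpression("g", "i", [0, 2, 4, 6], [5, 5, 5, 5])
        assert diel_range(s) == 0.0

    def test_sinusoid_on_field_grid(self, field_times):
        y = 5 + 2 * np.sin(2 * np.pi * field_times / 24)
        s = TimeSeriesExpression("g", "i", field_times, y)
        # grid hits the extremes at t=6 and t=18 exactly
        assert diel_range(s) == pytest.approx(4.0)

    def test_replicates_averaged_before_range(self):
        s = TimeSeriesExpression("g", "i", [0, 2, 0, 2], [1, 5, 3, 7],
                                 replicate=[0, 0, 1, 1])
        assert diel_range(s) == pytest.approx(4.0)  # means 2 and 6

    def test_single_timepoint_is_zero(self):
        s = TimeSeriesExpression("g", "i", [4.0], [2.0])
        assert diel_range(s) == 0.0


class TestKwStatistic:
    def test_textbook_six_point_case(self):
        h = kw_statistic([1, 2, 3, 4, 5, 6], list("AAABBB"))
        # rank-sum formula: 12/(6*7) * (6^2/3 + 15^2/3) - 3*7
        assert h == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21)

    def test_all_equal_convention(self):
        assert kw_statistic([2, 2, 2, 2], list("AABB")) == 0.0

    def test_matches_scipy_with_ties(self, rng):
        values = rng.integers(0, 5, size=30).astype(float)
        groups = rng.choice(list("ABC"), size=30)
        expected = stats.kruskal(
            *[values[groups == g] for g in "ABC"]).statistic
        assert kw_statistic(values, groups) == pytest.approx(expected)

    def test_label_symmetry(self, rng):
        values = rng.normal(size=12)
        groups = list("AAABBBCCCDDD")
        perm = rng.permutation(12)
        assert kw_statistic(values, groups) == pytest.approx(
            kw_statistic(values[perm], np.asarray(groups)[perm]))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            kw_statistic([1, 2, 3], list("AAA"))


class TestKwPermutation:
    def test_exhaustive_six_point_case(self):
        p = kw_permutation_p([1, 2, 3, 4, 5, 6], list("AAABBB"))
        assert p == pytest.approx(2 / 20)

    def test_sampling_converges_to_exhaustive(self):
        values = [1, 2, 3, 4, 5, 6]
        groups = list("AAABBB")
        exact = kw_permutation_p(values, groups)
        sampled = kw_permutation_p(values, groups, n_perm=20000, seed=1,
                                   exhaustive_limit=1)
        assert abs(sampled - exact) < 3 * np.sqrt(exact * (1 - exact)
                                                  / 20000) + 1e-4

    def test_matches_independent_enumeration(self, rng):
        values = rng.normal(size=7)
        groups = list("AABBBCC")
        assert kw_permutation_p(values, groups, exhaustive_limit=1000) \
            == pytest.approx(exhaustive_kw_p(values, groups))

    def test_zero_statistic_gives_p_one(self):
        assert kw_permutation_p([3, 3, 3, 3, 3, 3], list("AAABBB")) == 1.0

    def test_sampling_floor(self, rng):
        values = np.concatenate([rng.normal(0, 1, 10),
                                 rng.normal(40, 1, 10)])
        groups = ["A"] * 10 + ["B"] * 10
        p = kw_permutation_p(values, groups, n_perm=500, seed=0)
        assert p >= 1 / 501

    def test_null_p_roughly_uniform(self, rng):
        pvals = []
        for _ in range(200):
            values = rng.normal(size=12)
            groups = rng.permutation(list("AAAABBBBCCCC"))
            pvals.append(kw_permutation_p(values, groups, n_perm=300,
                                          seed=rng.integers(2 ** 31)))
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3


class TestIdentifyDdr:
    def _inputs(self, responses, haps, cyc_p, baselines):
        idx = [f"I{i:02d}" for i in range(len(responses))]
        return (pd.Series(responses, index=idx),
                pd.Series(haps, index=idx),
                pd.Series(cyc_p, index=idx),
                pd.Series(baselines, index=idx))

    def test_strong_separation_called(self, rng):
        n = 24
        haps = ["A"] * 12 + ["B"] * 12
        responses = np.r_[rng.normal(0.5, 0.1, 12),
                          rng.normal(6.0, 0.3, 12)]
        res = identify_ddr("pg", *self._inputs(
            responses, haps, [0.001] * n, [100.0] * n), seed=0)
        assert res.is_candidate
        assert res.perm_pvalue < 0.05

    def test_cycling_filter_blocks_candidacy(self, rng):
        n = 24
        haps = ["A"] * 12 + ["B"] * 12
        responses = np.r_[rng.normal(0.5, 0.1, 12),
                          rng.normal(6.0, 0.3, 12)]
        cyc = [0.001] * 5 + [0.5] * (n - 5)  # only 5 cycling inbreds
        res = identify_ddr("pg", *self._inputs(
            responses, haps, cyc, [100.0] * n), seed=0)
        assert res.perm_pvalue < 0.05
        assert not res.is_candidate

    def test_expression_floor_blocks_candidacy(self, rng):
        n = 24
        haps = ["A"] * 12 + ["B"] * 12
        responses = np.r_[rng.normal(0.5, 0.1, 12),
                          rng.normal(6.0, 0.3, 12)]
        low = [10.0] * n
        res = identify_ddr("pg", *self._inputs(
            responses, haps, [0.001] * n, low), seed=0)
        assert not res.is_candidate

    def test_single_haplotype_untestable(self):
        res = identify_ddr("pg", *self._inputs(
            [1, 2, 3, 4], ["A"] * 4, [0.001] * 4, [100] * 4), seed=0)
        assert np.isnan(res.perm_pvalue)
        assert not res.is_candidate

    def test_invariant_to_inbred_order_and_hap_names(self, rng):
        n = 12
        responses = rng.normal(2, 1, n)
        haps = list("AAABBBABABAB")
        args = self._inputs(responses, haps, [0.001] * n, [100.0] * n)
        res1 = identify_ddr("pg", *args, seed=5)
        order = rng.permutation(n)
        shuffled = tuple(s.iloc[order] for s in args)
        res2 = identify_ddr("pg", *shuffled, seed=5)
        renamed = (args[0], args[1].map({"A": "x9", "B": "q1"}),
                   args[2], args[3])
        res3 = identify_ddr("pg", *renamed, seed=5)
        assert res1.kw_H == pytest.approx(res2.kw_H)
        assert res1.kw_H == pytest.approx(res3.kw_H)
        assert res1.perm_pvalue == pytest.approx(res2.perm_pvalue)
        assert res1.perm_pvalue == pytest.approx(res3.perm_pvalue)


class TestConfirmDdr:
    def _series(self, rng, amplitude, n_rep=2):
        t = np.arange(0.0, 31.0, 3.0)
        tt = np.tile(t, n_rep)
        y = 100 + amplitude * np.sin(2 * np.pi * tt / 24) \
            + rng.normal(0, 0.3, len(tt))
        return TimeSeriesExpression(
            "g", "x", tt, np.clip(y, 0, None),
            replicate=np.repeat(np.arange(n_rep), len(t)))

    def test_shared_haplotype_untested(self, rng):
        series = {g: self._series(rng, 1.0) for g in "abc"}
        status, p = confirm_ddr(series, {g: "H0" for g in "abc"})
        assert status == "untested" and np.isnan(p)

    def test_identical_series_not_significant(self, rng):
        s = self._series(rng, 2.0)
        series = {"a": s, "b": s}
        status, p = confirm_ddr(series, {"a": "H0", "b": "H1"})
        assert status == "tested"
        assert p > 0.9

    def test_three_haplotypes_min_p_power(self):
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(20):
            series = {"a": self._series(rng, 0.0),
                      "b": self._series(rng, 0.0),
                      "c": self._series(rng, 3.0)}
            status, p = confirm_ddr(
                series, {"a": "H0", "b": "H1", "c": "H2"})
            assert status == "tested"
            hits += p < 0.01
        assert hits >= 18

    def test_no_expression_untested(self):
        assert confirm_ddr({}, {"a": "H0"})[0] == "untested"


def test_ddr_scan_recovers_truth(small_dataset, small_rhythm):
    """End-to-end field scan on the shared synthetic study."""
    d = small_dataset
    res = ds.ddr_scan(d.field_expression, d.haplotypes, small_rhythm,
                      seed=3, n_perm=2000)
    called = set(res.loc[res.is_candidate, "pangene_id"])
    truth = d.truth.ddr_genes
    assert len(called & truth) / len(truth) >= 0.8
    # at this fixture size allow at most one false call
    assert len(called - truth) <= 1
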