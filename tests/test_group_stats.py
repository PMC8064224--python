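"""Two-sample tests, asymmetry contrast, repeated-measures ANOVA, Tukey HSD."""

import math

import numpy as np
import pandas as pd
import pytest

import retnorm as rn
from retnorm import geometry as geom
from retnorm.errors import (DataError, DegenerateDistributionError,
                            InsufficientDataError, ParameterError)

from conftest import grid_from_means


class TestTierAssignment:
    @pytest.mark.parametrize("p,tier", [
        (0.5, "ns"), (0.05, "ns"), (0.049999, "5%"), (0.01, "5%"),
        (0.009, "1%"), (0.001, "1%"), (0.0009, "0.1%"), (0.0, "0.1%"),
        (1.0, "ns"),
    ])
    def test_strict_thresholds(self, p, tier):
        """Boundaries are strict: p exactly at a threshold does not enter
        the more significant tier."""
        assert rn.tier_of(p) == tier

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            rn.tier_of(1.5)


class TestTwoSampleTest:
    def test_identical_samples_are_null(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = rn.two_sample_test(x, x)
        assert res.statistic == 0.0 and res.p == 1.0 and res.tier == "ns"

    def test_summary_form_equals_raw_form(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 2, size=40)
        b = rng.normal(11, 3, size=25)
        raw = rn.two_sample_test(a, b)
        summ = rn.two_sample_test((a.mean(), a.std(ddof=1), a.size),
                                  (b.mean(), b.std(ddof=1), b.size))
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-12)
        assert raw.p == pytest.approx(summ.p, rel=1e-12)
        assert raw.df == pytest.approx(summ.df, rel=1e-12)

    def test_group_difference_from_printed_summaries(self, wt_db, ad_db):
        """Inner nuclear layer at four months: WT 20.62(0.61) n=103 vs
        3xTg-AD 18.96(0.73) n=84 gives t about 16.6 and the strongest tier
        (independent summary-statistic oracle computed inline)."""
        a = wt_db.cell("WT", "combined", 4, "INL", "whole")
        b = ad_db.cell("3xTg-AD", "combined", 4, "INL", "whole")
        res = rn.two_sample_test(a, b)
        # oracle: Welch t from the printed numbers
        t_oracle = (20.62 - 18.96) / math.sqrt(0.61 ** 2 / 103 + 0.73 ** 2 / 84)
        assert res.statistic == pytest.approx(t_oracle, rel=1e-12)
        assert res.statistic == pytest.approx(16.6, abs=0.1)
        assert res.tier == "0.1%"

    def test_welch_df_bounded_by_pooled_df(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            na, nb = rng.integers(3, 30, size=2)
            a = rng.normal(0, rng.uniform(0.5, 3), size=na)
            b = rng.normal(0, rng.uniform(0.5, 3), size=nb)
            res = rn.two_sample_test(a, b)
            assert res.df <= na + nb - 2 + 1e-9

    def test_welch_df_attains_bound_when_balanced_equal_variance(self):
        res = rn.two_sample_test((10.0, 2.0, 30), (12.0, 2.0, 30))
        assert res.df == pytest.approx(58.0)

    def test_student_variant_pools(self):
        res = rn.two_sample_test((10.0, 2.0, 10), (12.0, 4.0, 20),
                                 variant="student")
        assert res.df == 28

    def test_degenerate_equal_constants_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            rn.two_sample_test((5.0, 0.0, 10), (5.0, 0.0, 10))

    def test_type_i_error_near_nominal(self):
        """Under the null, rejection at alpha = 0.05 happens in 5% +/- 2% of
        1,000 replicates at n = 30 per arm."""
        rng = np.random.default_rng(17)
        rejections = 0
        for _ in range(1000):
            a = rng.normal(0, 1, size=30)
            b = rng.normal(0, 1, size=30)
            rejections += rn.two_sample_test(a, b).p < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07


class TestAsymmetryTest:
    @staticmethod
    def _grids_from_slope(n_eyes, slope, noise_sd, seed):
        """Block grids of single-layer maps with a nasal-temporal gradient
        (built directly at map level; the generator's gradient term is the
        same linear form)."""
        rng = np.random.default_rng(seed)
        x = geom.nasal_temporal_coordinate(geom.GRID_SIZE, "OD")
        grids = []
        for i in range(n_eyes):
            values = (20.0 + slope * x[np.newaxis, :]
                      + rng.normal(0, noise_sd, size=(geom.GRID_SIZE,
                                                      geom.GRID_SIZE)))
            tmap = rn.ThicknessMap(layer="INL", values=values,
                                   validity=np.ones_like(values, dtype=bool),
                                   orientation="standardized",
                                   subject=f"e{i}")
            grids.append(rn.crop_and_block(tmap))
        return grids

    def test_null_rejection_rate_matches_alpha(self, make_block_grid):
        """Symmetric eyes: the paired contrast rejects at about the nominal
        5% rate over 500 simulated cohorts (grids built directly from
        random block means)."""
        rng = np.random.default_rng(23)
        rejections = 0
        for _ in range(500):
            grids = [make_block_grid(rng.normal(20, 1, size=(3, 3)),
                                     subject=f"e{i}") for i in range(12)]
            rejections += rn.asymmetry_test(grids).p < 0.05
        assert 0.025 <= rejections / 500 <= 0.075

    def test_nasal_gradient_detected(self):
        """A 2 um nasal-temporal slope with 2 um map noise is detected at
        tier 5% or better with 50 eyes."""
        grids = self._grids_from_slope(50, slope=2.0, noise_sd=2.0, seed=5)
        res = rn.asymmetry_test(grids)
        assert res.mean_difference > 0
        assert res.tier != "ns"

    def test_single_eye_insufficient(self, make_block_grid):
        grid = make_block_grid(np.full((3, 3), 20.0))
        with pytest.raises(InsufficientDataError):
            rn.asymmetry_test([grid])

    def test_eyes_without_valid_columns_are_dropped(self, make_block_grid):
        means = np.full((3, 3), 20.0)
        no_nasal = means.copy()
        no_nasal[:, 2] = np.nan
        grids = [make_block_grid(no_nasal, subject="broken")] + \
            [make_block_grid(means + np.random.default_rng(i).normal(0, 1, (3, 3)),
                             subject=f"e{i}") for i in range(3)]
        res = rn.asymmetry_test(grids)
        assert res.df == 2  # 3 usable eyes


class TestRanova:
    def test_constant_over_time_is_exact_null(self):
        y = np.tile([[3.0], [5.0], [9.0]], (1, 4))  # subjects differ, time flat
        res = rn.ranova(y)
        assert res.F == 0.0 and res.p == 1.0

    def test_toy_table_matches_brute_force_decomposition(self):
        """3 subjects x 4 ages: F equals the explicitly summed
        sums-of-squares decomposition."""
        y = np.array([[10.0, 12.0, 11.0, 13.0],
                      [9.0, 11.5, 10.0, 12.0],
                      [11.0, 13.0, 12.5, 14.0]])
        n, k = y.shape
        grand = y.sum() / y.size
        ss_time = sum(n * (y[:, j].sum() / n - grand) ** 2 for j in range(k))
        ss_subj = sum(k * (y[i, :].sum() / k - grand) ** 2 for i in range(n))
        ss_total = sum((y[i, j] - grand) ** 2
                       for i in range(n) for j in range(k))
        ss_err = ss_total - ss_time - ss_subj
        f_oracle = (ss_time / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        res = rn.ranova(y)
        assert res.F == pytest.approx(f_oracle, rel=1e-12)
        assert res.df_time == 3 and res.df_error == 6

    def test_matches_pingouin(self):
        """Independent cross-check against an established implementation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        y = rng.normal(200, 3, size=(12, 4)) + np.array([0, -2, -3, -4.0])
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 4),
            "age": np.tile(np.arange(4), 12),
            "value": y.ravel()})
        aov = pingouin.rm_anova(data=long, dv="value", within="age",
                                subject="subject", correction=True)
        res = rn.ranova(y)
        assert res.F == pytest.approx(float(aov["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(aov["p_unc"].iloc[0]), rel=1e-9)
        assert res.gg_epsilon == pytest.approx(float(aov["eps"].iloc[0]),
                                               rel=1e-6)

    def test_incomplete_rows_are_contract_violation(self):
        y = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, np.nan, 3.0, 4.0],
                      [2.0, 3.0, 4.0, 5.0]])
        with pytest.raises(DataError):
            rn.ranova(y)

    def test_duplicated_single_subject_is_degenerate(self):
        row = np.array([10.0, 12.0, 11.0, 13.0])
        y = np.tile(row, (5, 1))
        with pytest.raises(DegenerateDistributionError):
            rn.ranova(y)

    def test_too_few_subjects(self):
        with pytest.raises(InsufficientDataError):
            rn.ranova(np.ones((2, 4)))

    def test_type_i_error_near_nominal(self):
        """No time effect, n = 30 subjects: rejection at alpha = 0.05 in
        5% +/- 2% of 1,000 replicates."""
        rng = np.random.default_rng(29)
        rejections = 0
        for _ in range(1000):
            y = rng.normal(0, 1, size=(30, 4)) + rng.normal(0, 2, size=(30, 1))
            rejections += rn.ranova(y).p < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07


class TestTukeyPairwise:
    def test_equal_means_nothing_significant(self):
        rng = np.random.default_rng(4)
        y = rng.normal(100, 1, size=(20, 4))
        results = rn.tukey_pairwise(y)
        assert len(results) == 6
        # equal population means: no pair should reach even tier 5% often;
        # with this seed none does
        assert all(r.tier == "ns" for r in results.values())

    def test_large_shift_hits_strongest_tier(self):
        """Shifting one age by 10 within-subject error sds makes all three
        of its pairs significant at 0.1% with n = 30."""
        rng = np.random.default_rng(6)
        y = rng.normal(0, 1, size=(30, 4)) + rng.normal(0, 3, size=(30, 1))
        y[:, 2] += 10.0
        results = rn.tukey_pairwise(y)
        involving = [r for pair, r in results.items() if 3 in pair]
        assert len(involving) == 3
        assert all(r.tier == "0.1%" for r in involving)
        others = [r for pair, r in results.items() if 3 not in pair]
        assert all(r.tier == "ns" for r in others)

    def test_tukey_p_dominates_unadjusted_pooled_t(self):
        """Correction monotonicity: each Tukey p is at least the unadjusted
        two-sided t p for the same contrast on the same pooled error term."""
        from scipy import stats

        rng = np.random.default_rng(7)
        y = rng.normal(50, 2, size=(15, 4)) + np.array([0.0, 0.5, 1.0, 1.5])
        results = rn.tukey_pairwise(y)
        # q = t * sqrt(2) for the same contrast on the same error term
        for r in results.values():
            t_equiv = r.statistic / math.sqrt(2.0)
            p_unadj = 2 * stats.t.sf(t_equiv, r.df)
            assert r.p >= p_unadj - 1e-12

    def test_matches_statsmodels_on_group_means(self):
        """The studentized-range tail matches an established Tukey HSD when
        fed the same error term (balanced one-way layout equivalence)."""
        from scipy import stats

        q = 4.2
        p_scipy = stats.studentized_range.sf(q, 4, 30)
        # statsmodels' internal q-distribution
        from statsmodels.stats.libqsturng import psturng

        p_sm = float(np.atleast_1d(psturng(q, 4, 30))[0])
        assert p_scipy == pytest.approx(p_sm, abs=5e-3)


class TestSelectCompleteCases:
    def test_all_complete_nothing_dropped(self):
        records = pd.DataFrame({
            "subject": np.repeat(["a", "b"], 4),
            "age_months": [1, 2, 3, 4] * 2,
            "value": np.arange(8.0)})
        table = rn.select_complete_cases(records)
        assert table.dropped == 0 and len(table.data) == 2
        assert table.ages == (1, 2, 3, 4)

    def test_missing_visit_drops_subject(self):
        records = pd.DataFrame({
            "subject": ["a"] * 4 + ["b"] * 3,
            "age_months": [1, 2, 3, 4, 1, 2, 4],
            "value": np.arange(7.0)})
        table = rn.select_complete_cases(records)
        assert table.dropped == 1
        assert list(table.data.index) == ["a"]

    def test_empty_input(self):
        records = pd.DataFrame(columns=["subject", "age_months", "value"])
        table = rn.select_complete_cases(records)
        assert table.dropped == 0 and len(table.data) == 0

    def test_feeds_ranova(self):
        rng = np.random.default_rng(11)
        subjects = [f"s{i}" for i in range(6)]
        records = pd.DataFrame({
            "subject": np.repeat(subjects, 4),
            "age_months": list(rn.geometry.AGES_MONTHS) * 6,
            "value": rng.normal(200, 3, size=24)})
        table = rn.select_complete_cases(records)
        res = rn.ranova(table)
        assert 0.0 <= res.p <= 1.0
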