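"""Statistical machinery, each routine checked against an independent oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfindex.datagen import LesionRecord
from pfindex.stats import (
    chi_square_prop,
    mad_outlier_flags,
    ols_fit,
    one_way_anova,
    pooled_mean,
    prediction_accuracy,
    summarize_strata,
)


def _lesion(i, depth, pfi=None, dose=3, force=30.0, target=None, width=10.0, excluded=False,
            reason=None):
    return LesionRecord(
        lesion_id=f"L{i}", animal_id="S01", chamber="RV", mean_cf_g=force,
        n_applications=dose, attained_pfi=pfi if pfi is not None else 100.0 * depth,
        depth_mm=depth, width_mm=width, intended_pfi_target=target,
        excluded=excluded, exclusion_reason=reason,
    )


# --------------------------------------------------------------------------
# OLS
# --------------------------------------------------------------------------


def _grid_search_ols(x, y):
    """Brute-force oracle: nested grid refinement over (slope, intercept)."""
    best = (0.0, 0.0)
    span = 20.0
    for _ in range(14):
        slopes = np.linspace(best[0] - span, best[0] + span, 41)
        intercepts = np.linspace(best[1] - span, best[1] + span, 41)
        rss = [
            (float(np.sum((y - (b + m * x)) ** 2)), m, b)
            for m in slopes
            for b in intercepts
        ]
        _, m, b = min(rss)
        best, span = (m, b), span / 3.0
    return best


class TestOls:
    def test_exact_line(self):
        fit = ols_fit([1, 2, 3], [2, 4, 6])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        fit = ols_fit([1, 2, 3, 4], [5, 5, 5, 5])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            x = rng.uniform(0, 10, 10)
            y = 1.5 * x - 2.0 + rng.normal(0, 1.0, 10)
            fit = ols_fit(x, y)
            m, b = _grid_search_ols(x, y)
            assert fit.slope == pytest.approx(m, abs=1e-3)
            assert fit.intercept == pytest.approx(b, abs=1e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ols_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ols_fit([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            ols_fit([1, 2, 3], [1, 2])


# --------------------------------------------------------------------------
# ANOVA
# --------------------------------------------------------------------------


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        f, p = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_group_f_equals_pooled_t_squared(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [3.0, 4.0, 5.0, 6.0]
        # hand-computed pooled-variance t on a 4+4 sample
        ma, mb = np.mean(a), np.mean(b)
        sp2 = (np.var(a, ddof=1) * 3 + np.var(b, ddof=1) * 3) / 6
        t = (ma - mb) / math.sqrt(sp2 * (0.25 + 0.25))
        f, _ = one_way_anova([a, b])
        assert f == pytest.approx(t**2, rel=1e-9)

    def test_sum_of_squares_decomposition(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1.0, n) for m, n in [(0, 5), (1, 7), (2, 6)]]
        allv = np.concatenate(groups)
        grand = allv.mean()
        ss_total = np.sum((allv - grand) ** 2)
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
        assert ss_total == pytest.approx(ss_between + ss_within, rel=1e-9)
        f, _ = one_way_anova(groups)
        assert f == pytest.approx((ss_between / 2) / (ss_within / (len(allv) - 3)), rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])


# --------------------------------------------------------------------------
# Chi-square
# --------------------------------------------------------------------------


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        chi2, p = chi_square_prop([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0)

    def test_hand_computed_2x2(self):
        # rows (10,20)/(20,10): all expected counts are 15, so
        # chi2 = 4 * (10-15)^2/15 = 20/3
        chi2, p = chi_square_prop([[10, 20], [20, 10]])
        expected = 4 * (10 - 15) ** 2 / 15
        assert chi2 == pytest.approx(expected, rel=1e-12)
        assert 0 < p < 0.05

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            chi_square_prop([[10], [20]])
        with pytest.raises(ValueError):
            chi_square_prop([[0, 0], [1, 2]])


# --------------------------------------------------------------------------
# MAD outliers
# --------------------------------------------------------------------------


class TestMadOutliers:
    def test_identical_values_never_flagged(self):
        flags = mad_outlier_flags([2.0] * 5, ["a"] * 5)
        assert not flags.any()

    def test_hand_computed_group(self):
        # median 3.05, |dev| = (.05,.05,.15,5.95), MAD = .10 -> scaled .14826
        # k=3 threshold 0.4448: only 9.0 exceeds it
        flags = mad_outlier_flags([3.0, 3.1, 2.9, 9.0], ["g"] * 4, k=3.0)
        assert flags.tolist() == [False, False, False, True]

    def test_grouping_is_respected(self):
        # 9.0 is extreme in group a but the norm in group b
        values = [3.0, 3.1, 2.9, 9.0, 9.0, 9.1, 8.9]
        labels = ["a", "a", "a", "a", "b", "b", "b"]
        flags = mad_outlier_flags(values, labels)
        assert flags.tolist() == [False, False, False, True, False, False, False]

    def test_small_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            flags = mad_outlier_flags([1.0, 100.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b", "b"])
        assert not flags.any()


# --------------------------------------------------------------------------
# Prediction accuracy
# --------------------------------------------------------------------------


class TestPredictionAccuracy:
    def test_exact_predictions_score_one(self):
        lesions = [_lesion(i, depth=3.0, pfi=300.0) for i in range(5)]
        frac, num, den = prediction_accuracy(lesions, 2.0)
        assert (frac, num, den) == (1.0, 5, 5)

    def test_uniform_offset_beyond_tolerance_scores_zero(self):
        lesions = [_lesion(i, depth=5.5, pfi=300.0) for i in range(4)]
        frac, _, _ = prediction_accuracy(lesions, 2.0)
        assert frac == 0.0

    def test_excluded_lesions_do_not_count(self):
        lesions = [_lesion(0, 3.0, 300.0),
                   _lesion(1, 9.0, 300.0, excluded=True, reason="transmural")]
        frac, num, den = prediction_accuracy(lesions, 2.0)
        assert (num, den) == (1, 1)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=8), min_size=3, max_size=20))
    def test_monotone_in_tolerance(self, depths):
        lesions = [_lesion(i, d, pfi=350.0) for i, d in enumerate(depths)]
        fracs = [prediction_accuracy(lesions, tol)[0] for tol in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))


# --------------------------------------------------------------------------
# Strata summaries
# --------------------------------------------------------------------------


class TestSummaries:
    def test_published_pfi_strata_pool_to_424(self):
        assert pooled_mean([29, 23, 21], [307, 460, 547]) == pytest.approx(424, abs=0.5)

    def test_published_depth_strata_pool_to_3_6(self):
        assert pooled_mean([29, 23, 21], [2.86, 3.92, 4.41]) == pytest.approx(3.6, abs=0.05)

    def test_pooled_row_reproduces_weighted_mean_identity(self):
        lesions = (
            [_lesion(i, 2.0, dose=3) for i in range(4)]
            + [_lesion(10 + i, 5.0, dose=12) for i in range(2)]
        )
        rows = summarize_strata(lesions, "dose", "depth")
        pooled = rows[-1]
        assert pooled.group_label == "pooled"
        assert pooled.mean == pytest.approx((4 * 2.0 + 2 * 5.0) / 6, rel=1e-12)
        assert pooled.n == 6

    def test_single_stratum_pooled_row_matches_it(self):
        lesions = [_lesion(i, float(i + 1), dose=6) for i in range(4)]
        rows = summarize_strata(lesions, "dose", "depth")
        assert rows[0].mean == rows[-1].mean
        assert rows[0].n == rows[-1].n

    def test_unknown_keys_rejected(self):
        lesions = [_lesion(0, 1.0)]
        with pytest.raises(ValueError):
            summarize_strata(lesions, "bogus", "depth")
        with pytest.raises(ValueError):
            summarize_strata(lesions, "dose", "bogus")
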