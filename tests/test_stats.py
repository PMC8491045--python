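"""Rank test, exact test, conditional-MLE OR, Spearman, logistic, battery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given
from hypothesis import strategies as st

from vbmorph import (ContingencyTable2x2, EffectConfig, analysis_battery,
                     fisher_exact_2x2, fit_logistic, generate_cohort,
                     mann_whitney, spearman_assoc)
from vbmorph.stats import effect_size_r, odds_ratio_from_coef
from vbmorph.wmh import score_cohort


class TestMannWhitney:
    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 35)
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tie_correction_matches_scipy(self):
        x = [1, 2, 2, 3, 3, 3, 4]
        y = [2, 3, 3, 4, 4, 5]
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_identical_samples_give_central_u_and_zero_z(self):
        x = [5.0, 5.0, 5.0]
        res = mann_whitney(x, x)
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)
        assert res.z == 0.0

    def test_small_sample_approximation_close_to_permutation_oracle(self):
        # brute-force: all C(8,4) relabelings of the pooled sample
        x = [1.0, 3.0, 5.0, 7.0]
        y = [2.0, 4.0, 6.0, 8.0]
        pooled = np.array(x + y)
        obs_u = mann_whitney(x, y).statistic
        us = []
        for idx in itertools.combinations(range(8), 4):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(8) if i not in idx]]
            us.append(mann_whitney(xs, ys).statistic)
        exact_p = np.mean([u <= obs_u for u in us])
        # at n=4+4 the continuity-corrected approximation is the one designed
        # to track the exact permutation p
        approx_p = mann_whitney(x, y, continuity=True).p
        assert abs(approx_p - exact_p) <= 0.05

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=12),
           st.lists(st.floats(-50, 50), min_size=1, max_size=12))
    def test_u_orientations_sum_to_nxny(self, x, y):
        res = mann_whitney(x, y)
        assert res.extra["U_x"] + res.extra["U_y"] == pytest.approx(len(x) * len(y))
        assert res.r == pytest.approx(abs(res.z) / math.sqrt(len(x) + len(y)))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def enumerate_fisher_p(a, b, c, d):
    """Independent oracle: exhaustive fixed-margin enumeration with
    factorial probabilities."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    supp = range(max(0, c1 - r2), min(c1, r1) + 1)
    def prob(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)
    p_obs = prob(a)
    return sum(p for p in map(prob, supp) if p <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_p_matches_enumeration_oracle_small_tables(self):
        for a, b, c, d in [(3, 2, 1, 4), (0, 5, 5, 0), (2, 2, 2, 2),
                           (7, 1, 2, 8), (1, 9, 3, 3)]:
            res = fisher_exact_2x2([[a, b], [c, d]])
            assert res.p == pytest.approx(enumerate_fisher_p(a, b, c, d), rel=1e-9)

    def test_p_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = rng.integers(0, 25, size=4)
            if t[:2].sum() == 0 or t[2:].sum() == 0 or t[0] + t[2] == 0 \
                    or t[1] + t[3] == 0:
                continue
            res = fisher_exact_2x2(t.reshape(2, 2))
            ref = sps.fisher_exact(t.reshape(2, 2))
            assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_cmle_or_matches_scipy_conditional(self):
        for tab in ([[115, 89], [11, 75]], [[34, 170], [4, 82]],
                    [[10, 3], [2, 15]], [[1, 5], [7, 2]]):
            res = fisher_exact_2x2(tab)
            ref = sps.contingency.odds_ratio(tab, kind="conditional")
            assert res.odds_ratio == pytest.approx(ref.statistic, rel=1e-6)

    def test_uniform_table(self):
        res = fisher_exact_2x2([[1, 1], [1, 1]])
        assert res.p == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_cells_flagged_zero_or_inf(self):
        assert fisher_exact_2x2([[0, 5], [5, 5]]).odds_ratio == 0.0
        assert fisher_exact_2x2([[5, 0], [5, 5]]).odds_ratio == math.inf
        res = fisher_exact_2x2([[0, 0], [3, 4]])  # empty row: not estimable
        assert math.isnan(res.odds_ratio) and res.p == 1.0

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15),
           st.integers(0, 15))
    def test_or_symmetries(self, a, b, c, d):
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        orig = fisher_exact_2x2([[a, b], [c, d]]).odds_ratio
        swapped_both = fisher_exact_2x2([[d, c], [b, a]]).odds_ratio
        row_swapped = fisher_exact_2x2([[c, d], [a, b]]).odds_ratio
        if math.isnan(orig):
            return
        if orig in (0.0, math.inf):
            assert swapped_both == orig
        else:
            assert swapped_both == pytest.approx(orig, rel=1e-6)
            assert row_swapped == pytest.approx(1.0 / orig, rel=1e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(1, -1, 2, 3)


class TestSpearman:
    def test_perfect_anticorrelation(self):
        a = ["left", "even", "right", "left", "even", "right"]
        b = ["right", "even", "left", "right", "even", "left"]
        res = spearman_assoc(a, b)
        assert res.statistic == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle_with_ties(self):
        a = [1, 2, 2, 3, 1, 3]
        b = [2, 1, 3, 3, 1, 2]
        ra, rb = sps.rankdata(a), sps.rankdata(b)
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert spearman_assoc(a, b).statistic == pytest.approx(oracle, rel=1e-12)

    def test_planted_cohort_anticorrelation(self):
        subs, _ = generate_cohort(EffectConfig(n=2000), seed=17)
        res = spearman_assoc(subs["dominance"], subs["curve_direction"])
        assert -0.66 <= res.statistic <= -0.46

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman_assoc([1, 1, 1], [1, 2, 3])


class TestLogistic:
    def test_or_transform_consistency(self):
        assert odds_ratio_from_coef(0.316) == pytest.approx(1.37, abs=0.005)

    def test_parameter_recovery_single_fit(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 5000)
        p = 1 / (1 + np.exp(-(-1.0 + 0.3 * x)))
        y = (rng.random(5000) < p).astype(float)
        res = fit_logistic(x[:, None], y, names=["x"])
        b, se, _ = res.coef["x"]
        assert abs(b - 0.3) <= 3 * se
        assert res.extra["odds_ratios"]["x"] == pytest.approx(math.exp(b))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            fit_logistic(np.arange(10.0)[:, None], np.zeros(10))

    def test_rank_deficient_design_rejected(self):
        x = np.arange(20.0)
        X = np.column_stack([x, 2 * x])
        y = (x > 10).astype(float)
        with pytest.raises(ValueError):
            fit_logistic(X, y)

    def test_perfect_separation_flagged(self):
        x = np.linspace(-2, 2, 30)
        y = (x > 0).astype(float)
        with pytest.raises(ValueError, match="separation"):
            fit_logistic(x[:, None], y)


class TestBattery:
    def test_planted_effects_recovered(self):
        subs, les = generate_cohort(EffectConfig(n=2000), seed=3)
        rep = analysis_battery(score_cohort(subs, les), les)
        sig = set(rep.loc[rep["significant"], "test"])
        assert "dominance_by_curve_spearman" in sig
        assert "va_laterality_by_dominance" in sig
        assert "ba_laterality_by_curve" in sig

    def test_report_contains_full_comparison_set(self):
        subs, les = generate_cohort(EffectConfig(n=500), seed=1)
        rep = analysis_battery(score_cohort(subs, les), les)
        names = set(rep["test"])
        for expected in ("age_by_group", "hypertension_by_group",
                         "diabetes_by_group", "hyperlipidemia_by_group",
                         "ba_length_by_group", "ba_tortuosity_by_group",
                         "ba_area_by_group", "va_laterality_by_dominance",
                         "ba_laterality_by_curve", "dominance_by_curve_spearman",
                         "pca_wmh_logistic_full"):
            assert expected in names
        assert (rep["p_bonferroni"] >= rep["p_raw"] - 1e-15).all()

    def test_single_subject_rejected(self):
        subs, les = generate_cohort(EffectConfig(n=1), seed=0)
        with pytest.raises(ValueError):
            analysis_battery(score_cohort(subs, les), les)

    def test_missing_columns_reported(self):
        with pytest.raises(ValueError, match="missing"):
            analysis_battery(pd.DataFrame({"age": [1, 2]}), pd.DataFrame())


def test_effect_size_r_identity():
    assert effect_size_r(7.67, 290) == pytest.approx(0.45, abs=0.005)
    rng = np.random.default_rng(2)
    res = mann_whitney(rng.normal(0, 1, 30), rng.normal(1, 1, 30))
    assert res.r == pytest.approx(abs(res.z) / math.sqrt(60))
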