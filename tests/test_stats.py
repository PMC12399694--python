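from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sst

import fwave as fw
from fwave.stats import (
    benjamini_hochberg,
    chi2_test,
    fisher_exact_2x2,
    km_estimate,
    logistic_fit_univariate,
    logrank,
    mann_whitney,
    roc_analysis,
)


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2/C(6,3) enumerated arrangements

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_p_matches_full_enumeration(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(loc=0.8, size=5)
        u_obs, p_obs = mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        ranks = sst.rankdata(pooled)
        n, m = len(x), len(y)
        mu = n * m / 2
        count = sum(
            1
            for idx in combinations(range(n + m), n)
            if abs(sum(ranks[list(idx)]) - n * (n + 1) / 2 - mu)
            >= abs(u_obs - mu) - 1e-12
        )
        assert p_obs == pytest.approx(count / comb(n + m, n))

    def test_large_sample_p_matches_scipy_asymptotic(self, rng):
        x = rng.normal(size=500)
        y = rng.normal(loc=0.1, size=480)
        u, p = mann_whitney(x, y)
        ref = sst.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_tied_data_p_matches_scipy(self, rng):
        x = rng.integers(0, 5, size=40).astype(float)
        y = rng.integers(0, 5, size=35).astype(float)
        _, p = mann_whitney(x, y)
        ref = sst.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(fw.ValidationError):
            mann_whitney([], [1.0])


class TestCategorical:
    def test_fisher_strong_association_direction(self):
        # antiarrhythmic-drug use at follow-up: absent in one group,
        # frequent in the other
        assert fisher_exact_2x2([[0, 54], [11, 15]]) < 0.001

    def test_fisher_no_association(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_fisher_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_fisher_matches_bruteforce_enumeration(self, rng):
        # independent oracle: hypergeometric enumeration via binomials
        for _ in range(50):
            a, b, c, d = rng.integers(0, 8, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            n = a + b + c + d
            p_tab = lambda k: (
                comb(a + b, k) * comb(c + d, (a + c) - k) / comb(n, a + c)
            )
            lo = max(0, (a + c) - (c + d))
            hi = min(a + b, a + c)
            p_obs = p_tab(a)
            oracle = sum(
                p_tab(k) for k in range(lo, hi + 1)
                if p_tab(k) <= p_obs * (1 + 1e-7)
            )
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(oracle)

    def test_fisher_matches_scipy(self, rng):
        for _ in range(25):
            t = rng.integers(0, 12, size=(2, 2))
            if min(t.sum(0).min(), t.sum(1).min()) == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(
                sst.fisher_exact(t)[1], rel=1e-9
            )

    def test_chi2_matches_scipy_without_correction(self, rng):
        t = [[20, 10], [8, 25]]
        stat, p = chi2_test(t)
        ref = sst.chi2_contingency(t, correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_chi2_continuity_flag(self):
        t = [[12, 5], [6, 14]]
        stat_c, _ = chi2_test(t, continuity=True)
        ref = sst.chi2_contingency(t, correction=True)
        assert stat_c == pytest.approx(ref.statistic)


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.direction == ">="

    def test_four_point_example(self):
        res = roc_analysis([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.cutoff == 3.0

    def test_auc_equals_normalized_u(self, rng):
        for _ in range(200):
            n1, n0 = rng.integers(5, 20, size=2)
            scores = rng.normal(size=n1 + n0)
            labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            res = roc_analysis(scores, labels, direction=">=")
            u, _ = mann_whitney(scores[labels == 1], scores[labels == 0])
            assert res.auc == pytest.approx(u / (n1 * n0), rel=1e-12)

    def test_cutoff_matches_exhaustive_search(self, rng):
        scores = rng.normal(size=60)
        labels = (scores + rng.normal(scale=1.0, size=60) > 0).astype(int)
        res = roc_analysis(scores, labels, direction=">=")
        best = max(
            (
                (
                    np.mean(scores[labels == 1] >= c)
                    + np.mean(scores[labels == 0] < c),
                    np.mean(scores[labels == 1] >= c),
                    -c,
                )
                for c in np.unique(scores)
            ),
        )
        assert res.cutoff == pytest.approx(-best[2])
        se_sp = res.sensitivity + res.specificity
        assert se_sp == pytest.approx(best[0])

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        if labels.sum() in (0, 100):
            labels[0] = 1 - labels[0]
        res = roc_analysis(scores, labels, direction=">=")
        assert res.auc == pytest.approx(roc_auc_score(labels, scores), rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(fw.ValidationError):
            roc_analysis([1.0, 2.0], [1, 1])


class TestLogistic:
    def test_binary_predictor_matches_crossproduct_odds_ratio(self):
        a, b, c, d = 13, 7, 5, 17  # exposed/unexposed by outcome
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        fit = logistic_fit_univariate(x, y, increment=1.0)
        assert fit.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=200)
        y = (rng.uniform(size=200) < 1 / (1 + np.exp(-(0.5 + 1.2 * x)))).astype(int)
        fit = logistic_fit_univariate(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.coefficient == pytest.approx(ref.params[1], rel=1e-5)
        assert fit.se == pytest.approx(ref.bse[1], rel=1e-4)
        assert fit.p_value == pytest.approx(ref.pvalues[1], abs=1e-5)

    def test_constant_predictor_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            fit = logistic_fit_univariate([1.0] * 10, [0, 1] * 5)
        assert fit.degenerate
        assert np.isnan(fit.odds_ratio)

    def test_complete_separation_flagged(self):
        with pytest.warns(UserWarning, match="separation"):
            fit = logistic_fit_univariate(
                [0.0, 0.1, 0.2, 1.0, 1.1, 1.2], [0, 0, 0, 1, 1, 1]
            )
        assert fit.separated
        assert not np.isfinite(fit.odds_ratio) or fit.odds_ratio == 0.0

    def test_or_reported_per_increment(self, rng):
        x = rng.normal(loc=0.04, scale=0.01, size=150)
        y = (rng.uniform(size=150) < 1 / (1 + np.exp(-(50 * (x - 0.04))))).astype(int)
        if len(np.unique(y)) < 2:
            y[:2] = [0, 1]
        fit = logistic_fit_univariate(x, y, increment=0.01)
        assert fit.odds_ratio == pytest.approx(np.exp(fit.coefficient * 0.01))


class TestSurvival:
    def test_three_event_product_limit(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_all_censored_survival_stays_one(self):
        curve = km_estimate([5.0, 7.0, 9.0], [0, 0, 0])
        assert len(curve.event_times) == 0
        assert curve.survival_at(100.0) == 1.0

    def test_identical_groups_logrank_null(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 0, 1, 1, 0]
        groups = [0, 0, 0, 1, 1, 1]
        stat, p = logrank(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_km_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(10, size=50)
        events = rng.integers(0, 2, size=50)
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), rel=1e-9
            )

    def test_logrank_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        t0 = rng.exponential(10, size=40)
        t1 = rng.exponential(20, size=35)
        e0 = rng.integers(0, 2, size=40)
        e1 = rng.integers(0, 2, size=35)
        times = np.r_[t0, t1]
        events = np.r_[e0, e1]
        groups = np.r_[np.zeros(40, int), np.ones(35, int)]
        stat, p = logrank(times, events, groups)
        ref = logrank_test(t0, t1, event_observed_A=e0, event_observed_B=e1)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)


class TestCohortAnalyses:
    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=25)
        adj = benjamini_hochberg(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, ref, rtol=1e-12)

    def test_group_comparison_shape_and_signal(self, small_cohort):
        df = fw.compare_groups(small_cohort)
        assert {"feature", "success_median", "failure_median", "p_value"} <= set(
            df.columns
        )
        row = df.set_index("feature").loc["meanfwa_endwpvi"]
        assert row["success_median"] > row["failure_median"]

    def test_predictor_analysis_auc_scale(self, small_cohort):
        df = fw.predictor_analysis(small_cohort).set_index("predictor")
        assert (df["auc_pct"] >= 50).all()
        assert (df["auc_pct"] <= 100).all()
        # the end-of-procedure meanfWA separates groups in the generator
        assert df.loc["meanfwa_endwpvi", "auc_pct"] > 55


@given(
    st.lists(st.floats(-50, 50), min_size=2, max_size=12),
    st.lists(st.floats(-50, 50), min_size=2, max_size=12),
)
def test_mann_whitney_u_pair_identity(x, y):
    """U_xy + U_yx == n*m regardless of ties."""
    u_xy, _ = mann_whitney(x, y)
    u_yx, _ = mann_whitney(y, x)
    assert u_xy + u_yx == pytest.approx(len(x) * len(y))
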