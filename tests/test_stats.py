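"""Design calculations and cluster-aware analyses, checked against independent
oracles (hand-written IRLS logistic, closed-form OLS)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dxearly.errors import DomainError, FitError, SchemaError
from dxearly.simulate import StudyDesign, simulate_study
from dxearly.stats import (
    accuracy_summary,
    adjust_sample_size,
    cluster_bootstrap_or,
    cluster_linear,
    design_effect,
    estimate_icc_anova,
    gee_logistic,
    order_effect_check,
    session_effect,
    session_effect_linear,
)


def irls_logistic(y, X, tol=1e-12, maxiter=200):
    """Independent oracle: plain Newton-Raphson logistic MLE."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        step = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (y - p))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestDesignEffect:
    @pytest.mark.parametrize(
        "n, icc, expected",
        [(6, 0.05, 1.25), (1, 0.7, 1.0), (12, 0.0, 1.0), (12, 0.05, 1.55)],
    )
    def test_values(self, n, icc, expected):
        assert design_effect(n, icc) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n, icc", [(0, 0.1), (5, -0.01), (5, 1.0)])
    def test_domain(self, n, icc):
        with pytest.raises(DomainError):
            design_effect(n, icc)

    @given(
        st.integers(1, 500),
        st.integers(1, 500),
        st.floats(0, 0.99),
        st.floats(0, 0.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_affine_in_icc_and_monotone_in_n(self, n1, n2, r1, r2):
        # affine: DE(n, (r1+r2)/2) is the average of DE(n, r1), DE(n, r2)
        mid = design_effect(n1, (r1 + r2) / 2)
        assert mid == pytest.approx((design_effect(n1, r1) + design_effect(n1, r2)) / 2, rel=1e-9)
        lo, hi = sorted((n1, n2))
        assert design_effect(lo, r1) <= design_effect(hi, r1) + 1e-12


class TestAdjustSampleSize:
    @pytest.mark.parametrize("base, de, expected", [(26, 1.25, 33), (10, 1.0, 10), (7, 1.5, 11)])
    def test_values(self, base, de, expected):
        assert adjust_sample_size(base, de) == expected

    def test_de_below_one_rejected(self):
        with pytest.raises(DomainError):
            adjust_sample_size(10, 0.9)


class TestAccuracySummary:
    @staticmethod
    def table(k0, k1, n=204):
        rows = [{"session": "baseline", "correct_working": int(i < k0)} for i in range(n)]
        rows += [{"session": "dss", "correct_working": int(i < k1)} for i in range(n)]
        return pd.DataFrame(rows)

    def test_counts_and_percentages(self):
        out = accuracy_summary(self.table(101, 119))
        assert out.loc["baseline", "count_correct"] == 101
        assert out.loc["baseline", "denominator"] == 204
        assert out.loc["baseline", "percent"] == 49.5
        assert out.loc["dss", "percent"] == 58.3

    def test_zero_and_half_up_rounding(self):
        out = accuracy_summary(self.table(0, 1, n=16))
        assert out.loc["baseline", "percent"] == 0.0
        assert out.loc["dss", "percent"] == 6.3  # 6.25 rounds half-up

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError, match="nope"):
            accuracy_summary(self.table(1, 1, n=4), "nope")

    def test_non_binary_rejected(self):
        t = self.table(1, 1, n=4)
        t.loc[0, "correct_working"] = 2
        with pytest.raises(SchemaError):
            accuracy_summary(t)


class TestGEELogistic:
    def test_matches_irls_oracle_one_obs_per_cluster(self):
        rng = np.random.default_rng(4)
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * X[:, 1])))).astype(float)
        fit = gee_logistic(y, X, groups=np.arange(n), corr="independence")
        assert fit.params == pytest.approx(irls_logistic(y, X), abs=1e-6)

    def test_no_effect_data_gives_or_one(self):
        # identical outcome pattern in both sessions
        y = np.tile([1, 0, 1, 1, 0, 0], 8)
        session = np.repeat([0.0, 1.0], 24)
        X = np.column_stack([np.ones(48), session])
        groups = np.repeat(np.arange(4), 12)
        fit = gee_logistic(y, X, groups, names=("const", "dss"))
        assert fit.params[1] == pytest.approx(0.0, abs=1e-8)
        assert fit.odds_ratios[1] == pytest.approx(1.0, abs=1e-8)

    def test_or_ci_transforms_consistently(self):
        table = simulate_study(StudyDesign(n_gps=30, seed=9))
        fit = session_effect(table)
        ci = fit.conf_int()
        orci = fit.or_conf_int()
        assert np.exp(ci) == pytest.approx(orci)
        assert (orci[:, 0] <= fit.odds_ratios).all() and (fit.odds_ratios <= orci[:, 1]).all()

    def test_large_sample_or_near_marginal_implied_value(self):
        """At 500 GPs the session OR approaches the value implied by the
        configured marginal accuracies pi0, pi1."""
        implied = (0.583 / (1 - 0.583)) / (0.495 / (1 - 0.495))
        table = simulate_study(StudyDesign(n_gps=500, seed=13))
        fit = session_effect(table)
        assert fit.odds_ratios[1] == pytest.approx(implied, abs=0.1)
        assert fit.converged

    def test_separation_raises_diagnostic_error(self):
        y = np.repeat([0.0, 1.0], 20)
        X = np.column_stack([np.ones(40), y])  # outcome perfectly explained
        with pytest.raises(FitError):
            gee_logistic(y, X, groups=np.arange(40), corr="independence")

    def test_singular_design_raises(self):
        y = np.tile([0.0, 1.0], 10)
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(FitError, match="singular"):
            gee_logistic(y, X, groups=np.arange(20))

    def test_two_clusters_minimum(self):
        with pytest.raises(DomainError):
            gee_logistic(np.array([0.0, 1.0]), np.ones((2, 1)), groups=np.zeros(2))


class TestClusterLinear:
    def test_constant_outcome_gives_zero_slope(self):
        y = np.full(24, 3.0)
        X = np.column_stack([np.ones(24), np.repeat([0.0, 1.0], 12)])
        fit = cluster_linear(y, X, groups=np.tile(np.arange(6), 4))
        assert fit.params[1] == pytest.approx(0.0, abs=1e-12)

    def test_one_obs_per_cluster_equals_ols_closed_form(self):
        rng = np.random.default_rng(11)
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 2.0 + 0.5 * X[:, 1] + rng.normal(size=n)
        fit = cluster_linear(y, X, groups=np.arange(n))
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.params == pytest.approx(beta, abs=1e-10)

    def test_coded_items_effect_matches_configured_means(self):
        """Session coefficient for items coded ~ 12.35 - 1.64 = 10.71."""
        table = simulate_study(StudyDesign(n_gps=500, seed=21))
        fit = session_effect_linear(table, "n_coded")
        assert fit.params[1] == pytest.approx(10.71, abs=0.5)

    def test_no_significant_increase_in_tests_or_duration(self):
        """With the configured small session shifts, CIs for tests/duration
        effects stay near the configured mean differences."""
        table = simulate_study(StudyDesign(n_gps=400, seed=22))
        for outcome, target in (("n_tests", 2.83 - 2.51), ("duration_min", 14.42 - 13.73)):
            fit = session_effect_linear(table, outcome)
            lo, hi = fit.conf_int()[1]
            assert lo <= target + 0.35 and hi >= target - 0.35


class TestOrderEffect:
    def test_null_data_gives_or_near_one(self):
        rng = np.random.default_rng(3)
        ors = []
        for s in rng.integers(2**31, size=8):
            t = simulate_study(StudyDesign(n_gps=40, aided_accuracy=0.495, seed=int(s)))
            fits = order_effect_check(t)
            ors.extend([fits["baseline"].odds_ratios[1], fits["dss"].odds_ratios[1]])
        assert np.mean(np.log(ors)) == pytest.approx(0.0, abs=0.08)

    def test_constructed_step_signal_detected(self):
        rng = np.random.default_rng(6)
        t = simulate_study(StudyDesign(n_gps=40, seed=7))
        order = t.groupby("session")["scenario_order"].transform(lambda s: s - s.min() + 1)
        # strong but stochastic step (a deterministic one would be separation)
        p = np.where(order > 3, 0.9, 0.2)
        t = t.assign(correct_working=(rng.random(len(t)) < p).astype(int))
        fits = order_effect_check(t)
        assert fits["baseline"].odds_ratios[1] > 1.5
        assert fits["dss"].odds_ratios[1] > 1.5


class TestICCEstimator:
    def test_independent_data_near_zero(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, size=3000)
        groups = np.repeat(np.arange(250), 12)
        assert estimate_icc_anova(y, groups) == pytest.approx(0.0, abs=0.02)

    def test_strongly_clustered_data(self):
        rng = np.random.default_rng(13)
        cluster_p = rng.choice([0.1, 0.9], size=300)
        y = (rng.random((300, 10)) < cluster_p[:, None]).astype(float).ravel()
        groups = np.repeat(np.arange(300), 10)
        # Var(p_i)=0.16, pbar=0.5 -> ICC = 0.16/0.25 = 0.64
        assert estimate_icc_anova(y, groups) == pytest.approx(0.64, abs=0.04)


class TestBootstrapCrossCheck:
    def test_bootstrap_ci_brackets_gee_point_estimate(self):
        table = simulate_study(StudyDesign(n_gps=40, seed=30))
        point, (lo, hi) = cluster_bootstrap_or(table, n_boot=60, seed=1)
        assert lo < point < hi
        fit = session_effect(table)
        assert point == pytest.approx(fit.odds_ratios[1])
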