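"""Misclassified-response logistic regression: likelihood, fit, selection, GOF."""

import logging

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

import rrsurvey as rs
from rrsurvey.glm import (
    RRLogisticRegression,
    build_design_matrix,
    fit_rr_model,
    odds_ratio_table,
    pearson_gof,
    pearson_statistic,
    rr_loglik,
    stepwise_select,
)


def _simulate_rows(seed, n=2000, beta=(-0.5, 1.0, 0.06), noise=True):
    """Two-arm dataset from a known latent model, as a respondent frame."""
    rng = np.random.default_rng(seed)
    arm = np.where(rng.random(n) < 0.5, "indirect", "direct")
    oc = rng.normal(7.34, 7.121, n).clip(0, 40)
    mu = expit(beta[0] + beta[1] * (arm == "indirect") + beta[2] * oc)
    c = np.where(arm == "indirect", 0.2, 0.0)
    d = np.where(arm == "indirect", 0.6, 1.0)
    y = (rng.random(n) < c + d * mu).astype(int)
    df = pd.DataFrame({"arm": arm, "oc_score": oc, "resp_theft": y})
    if noise:
        df["age"] = rng.normal(37, 9, n).clip(18, 55)  # unrelated to the outcome
    return df


class TestLogLikelihood:
    def test_reduces_to_bernoulli_logit(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = rng.integers(0, 2, 50).astype(float)
        beta = np.array([0.3, -0.7])
        ll, _ = rr_loglik(beta, X, y, c=0.0, d=1.0)
        mu = expit(X @ beta)
        expected = np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_single_row_at_beta_zero(self):
        # c + d/2 = 0.2 + 0.3 = 0.5 -> log(0.5)
        ll, _ = rr_loglik(np.zeros(1), np.ones((1, 1)), np.array([1.0]), 0.2, 0.6)
        assert ll == pytest.approx(np.log(0.5))

    def test_gradient_matches_finite_differences(self, rng):
        n, k = 20, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
        y = rng.integers(0, 2, n).astype(float)
        c = np.where(rng.random(n) < 0.5, 0.2, 0.0)
        d = np.where(c > 0, 0.6, 1.0)
        beta = rng.normal(scale=0.5, size=k)
        _, grad = rr_loglik(beta, X, y, c, d)
        h = 1e-6
        for j in range(k):
            e = np.zeros(k)
            e[j] = h
            fd = (rr_loglik(beta + e, X, y, c, d)[0] - rr_loglik(beta - e, X, y, c, d)[0]) / (2 * h)
            assert grad[j] == pytest.approx(fd, abs=1e-6)

    def test_finite_for_extreme_coefficients(self):
        X = np.array([[1.0, 100.0], [1.0, -100.0]])
        y = np.array([0.0, 1.0])
        ll, grad = rr_loglik(np.array([0.0, 5.0]), X, y, 0.0, 1.0)
        assert np.isfinite(ll) and np.all(np.isfinite(grad))


class TestFitting:
    def test_matches_irls_logistic_oracle(self, rng):
        # c=0, d=1 reduction on a seeded 200-row dataset
        X = rng.normal(size=(200, 3))
        eta = 0.3 + X @ [-0.5, 0.8, 0.2]
        y = (rng.random(200) < expit(eta)).astype(float)
        ours = RRLogisticRegression().fit(X, y)
        oracle = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(ours.params_, oracle.params, atol=1e-6)
        np.testing.assert_allclose(ours.bse_, oracle.bse, atol=1e-4)
        assert ours.converged_

    def test_coefficient_recovery_with_mixed_devices(self, tiny_mixed_dataset):
        # 200 replications: each true coefficient inside +/- 2 reported SEs
        # in >= 90% of fits
        true_beta = tiny_mixed_dataset["beta"]
        hits = np.zeros(3)
        reps = 200
        for i in range(reps):
            rng = np.random.default_rng(300_000 + i)
            n = 2000
            indicator = (rng.random(n) < 0.5).astype(float)
            oc = rng.normal(7.34, 7.121, n).clip(0, 40)
            mu = expit(true_beta[0] + true_beta[1] * indicator + true_beta[2] * oc)
            c = np.where(indicator == 1, 0.2, 0.0)
            d = np.where(indicator == 1, 0.6, 1.0)
            y = (rng.random(n) < c + d * mu).astype(float)
            fit = RRLogisticRegression().fit(
                np.column_stack([indicator, oc]), y, c=c, d=d
            )
            hits += np.abs(fit.params_ - true_beta) <= 2 * fit.bse_
        assert (hits / reps >= 0.90).all()

    def test_aic_identity_and_odds_ratios(self, tiny_mixed_dataset):
        td = tiny_mixed_dataset
        fit = RRLogisticRegression().fit(td["X"], td["y"], c=td["c"], d=td["d"])
        assert fit.aic_ == pytest.approx(2 * 3 - 2 * fit.loglik_, abs=1e-9)
        np.testing.assert_allclose(fit.odds_ratios_, np.exp(fit.params_))
        assert (fit.bse_ > 0).all()

    def test_gradient_small_at_reported_optimum(self, tiny_mixed_dataset):
        td = tiny_mixed_dataset
        fit = RRLogisticRegression().fit(td["X"], td["y"], c=td["c"], d=td["d"])
        Xd = np.column_stack([np.ones(len(td["y"])), td["X"]])
        _, grad = rr_loglik(fit.params_, Xd, td["y"], td["c"], td["d"])
        assert np.max(np.abs(grad)) < 1e-8
        assert fit.converged_

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([x, 2 * x])
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(ValueError, match="rank deficient"):
            RRLogisticRegression().fit(X, y, column_names=["a", "a_copy"])

    def test_reference_recoding_leaves_fitted_probabilities_invariant(self):
        df = _simulate_rows(seed=17, n=800)
        df["conduct"] = np.random.default_rng(18).choice(
            ["model", "acceptable", "wrong"], size=len(df)
        )
        fit = fit_rr_model(df, "theft", ["method", "conduct"])
        # recode the reference by relabelling so 'wrong' sorts first
        relab = df.copy()
        mapping = {"model": "wrong", "wrong": "model"}
        relab["conduct"] = relab["conduct"].map(lambda v: mapping.get(v, v))
        refit = fit_rr_model(relab, "theft", ["method", "conduct"])
        p_a = fit.model.predict_response_proba(
            build_design_matrix(df, fit.terms)[0]
        )
        p_b = refit.model.predict_response_proba(
            build_design_matrix(relab, refit.terms)[0]
        )
        assert np.max(np.abs(p_a - p_b)) < 1e-10


class TestStepwise:
    def test_noise_covariate_removed(self):
        # AIC drops a pure-noise term with probability P(chi2_1 < 2) ~ 0.84;
        # 500 replications resolve the rate well above 0.80
        removed = 0
        reps = 500
        for i in range(reps):
            df = _simulate_rows(seed=i)
            fit = stepwise_select(df, "theft", ["method", "oc_score", "age"])
            removed += "age" not in fit.terms
        assert removed / reps >= 0.80

    def test_local_minimum_is_fixed_point(self):
        df = _simulate_rows(seed=23, noise=False)
        base = stepwise_select(df, "theft", ["method", "oc_score"])
        again = stepwise_select(df, "theft", base.terms)
        assert sorted(again.terms) == sorted(base.terms)
        assert again.aic == pytest.approx(base.aic, abs=1e-9)

    def test_method_term_never_dropped(self):
        # outcome unrelated to the arm: method must still survive selection
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "arm": np.where(rng.random(1000) < 0.5, "indirect", "direct"),
                "oc_score": rng.normal(7, 7, 1000).clip(0, 40),
                "resp_theft": rng.integers(0, 2, 1000),
            }
        )
        fit = stepwise_select(df, "theft", ["method", "oc_score"])
        assert "method" in fit.terms

    def test_kept_term_must_be_a_candidate(self, survey_cohort):
        with pytest.raises(ValueError, match="method"):
            stepwise_select(survey_cohort, "theft", ["oc_score"])


class TestPearsonGOF:
    def test_perfect_fit_statistic_near_zero(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert pearson_statistic(y, y) < 1e-6

    def test_matches_classic_pearson_under_direct_design(self, rng):
        X = rng.normal(size=(300, 2))
        y = (rng.random(300) < expit(0.2 + X @ [0.7, -0.4])).astype(float)
        ours = RRLogisticRegression().fit(X, y)
        x2, _ = pearson_gof(ours, X, y)
        oracle = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        assert x2 == pytest.approx(oracle.pearson_chi2, abs=1e-8)

    def test_well_specified_model_is_not_spuriously_rejected(self):
        # For ungrouped binary data the statistic concentrates near its df,
        # so the chi-square p-value is conservative: no rejections at 0.05
        # expected across 100 well-specified replications
        ps = []
        for i in range(100):
            df = _simulate_rows(seed=600 + i, n=1000, noise=False)
            fit = fit_rr_model(df, "theft", ["method", "oc_score"])
            ps.append(fit.pearson_p)
        ps = np.array(ps)
        assert (ps < 0.05).mean() <= 0.05
        assert ps.min() > 0.01


class TestReporting:
    @pytest.mark.parametrize(
        "beta, exp_display",
        [(2.3169, "10.1442"), (0.0065, "1.0065"), (0.0, "1.0000")],
    )
    def test_exp_estimate_display(self, beta, exp_display, tiny_mixed_dataset):
        td = tiny_mixed_dataset
        fit = fit_rr_model(
            pd.DataFrame(
                {
                    "arm": np.where(td["X"][:, 0] == 1, "indirect", "direct"),
                    "oc_score": td["X"][:, 1],
                    "resp_theft": td["y"],
                }
            ),
            "theft",
            ["method", "oc_score"],
        )
        fit.beta = np.array([beta] * len(fit.beta))
        fit.odds_ratio = np.exp(fit.beta)
        table = odds_ratio_table(fit)
        assert (table["exp_estimate"] == exp_display).all()

    def test_table_rows_carry_term_labels(self, survey_cohort):
        fit = fit_rr_model(survey_cohort, "theft", ["method", "conduct", "oc_score"])
        table = odds_ratio_table(fit)
        assert list(table["term"]) == [
            "(Intercept)",
            "method[indirect]",
            "conduct[acceptable]",
            "conduct[wrong]",
            "oc_score",
        ]
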