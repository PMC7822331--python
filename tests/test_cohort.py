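"""Synthetic cohort generation, arm assignment, response mechanisms."""

import numpy as np
import pandas as pd
import pytest

import rrsurvey as rs
from rrsurvey.cohort import (
    BEHAVIOURS,
    CohortConfig,
    DEFAULT_DQ_REPORT_RATES,
    apply_response_mechanism,
    assign_arms,
    default_config,
    generate_cohort,
)
from rrsurvey.design import STUDY_DESIGN, direct_design


class TestGenerateCohort:
    def test_default_categorical_counts_are_exact(self):
        coh = generate_cohort(seed=4)
        assert len(coh) == 792
        assert coh["education"].value_counts().to_dict() == {
            "none": 125, "primary": 377, "secondary": 207, "higher": 83,
        }
        assert coh["conduct"].value_counts().to_dict() == {
            "model": 449, "acceptable": 301, "wrong": 42,
        }
        assert coh["nationality"].value_counts().to_dict() == {
            "spanish": 747, "other": 45,
        }
        crime = coh["crime"].value_counts().to_dict()
        assert crime["theft"] == 335 and crime["sex_crime"] == 52

    def test_continuous_covariates_respect_bounds(self):
        coh = generate_cohort(seed=4)
        assert coh["age"].between(18, 55).all()
        assert (coh["sentence_months"] >= 0).all()
        assert coh["oc_score"].between(0, 40).all()
        assert coh["oc_score"].dtype.kind == "i"

    def test_empty_cohort(self):
        coh = generate_cohort(default_config(n=0, covariate_marginals={}))
        assert len(coh) == 0

    def test_same_seed_identical_different_seed_differs(self):
        a = generate_cohort(seed=11)
        b = generate_cohort(seed=11)
        c = generate_cohort(seed=12)
        pd.testing.assert_frame_equal(a, b)
        assert not a["true_theft"].equals(c["true_theft"])

    def test_unknown_category_label_rejected(self):
        cfg = default_config()
        cfg.covariate_marginals["education"] = {"none": 792, "doctorate": 0}
        with pytest.raises(ValueError, match="doctorate"):
            generate_cohort(cfg)

    def test_count_marginals_must_sum_to_n(self):
        cfg = default_config()
        cfg.covariate_marginals["conduct"] = {"model": 500, "acceptable": 300, "wrong": 42}
        with pytest.raises(ValueError, match="conduct"):
            generate_cohort(cfg)

    def test_probability_marginals_accepted(self):
        cfg = default_config(n=200)
        cfg.covariate_marginals = {
            cov: {lvl: 1.0 / len(lvls) for lvl in lvls}
            for cov, lvls in rs.cohort.CATEGORICAL_LEVELS.items()
        }
        coh = generate_cohort(cfg, seed=3)
        assert len(coh) == 200

    def test_latent_prevalence_calibrated_to_target(self):
        # mean latent probability equals the configured prevalence exactly,
        # so realized statuses match it up to binomial noise
        coh = generate_cohort(seed=8)
        for b in BEHAVIOURS:
            target = rs.cohort.DEFAULT_BEHAVIOUR_MODELS[b].prevalence
            se = np.sqrt(target * (1 - target) / len(coh))
            assert abs(coh[f"true_{b}"].mean() - target) < 4 * max(se, 0.002)


class TestAssignArms:
    def test_even_split_halves_the_cohort(self):
        coh = assign_arms(generate_cohort(seed=1), 0.5, seed=2)
        assert (coh["arm"] == "indirect").sum() == 396
        assert (coh["arm"] == "direct").sum() == 396

    def test_odd_n_rounding_rule(self):
        coh = generate_cohort(default_config(n=3), seed=1)
        out = assign_arms(coh, 0.5, seed=0)
        # round(1.5) = 2 under numpy's banker rounding: indirect gets 2
        assert (out["arm"] == "indirect").sum() == 2
        assert (out["arm"] == "direct").sum() == 1

    def test_assignment_follows_row_positions_not_ids(self):
        coh = generate_cohort(default_config(n=50), seed=5)
        direct_ids = set(assign_arms(coh, 0.5, seed=9).query("arm=='direct'")["id"])
        shuffled = coh.iloc[::-1].reset_index(drop=True)
        direct_ids_shuffled = set(
            assign_arms(shuffled, 0.5, seed=9).query("arm=='direct'")["id"]
        )
        assert direct_ids != direct_ids_shuffled

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            assign_arms(generate_cohort(default_config(n=10), seed=0), 1.0)


class TestResponseMechanism:
    def test_no_bias_no_device_reproduces_truth(self):
        coh = assign_arms(generate_cohort(seed=6), seed=7)
        out = apply_response_mechanism(coh, direct_design(), dq_report_rate=1.0, seed=8)
        for b in BEHAVIOURS:
            np.testing.assert_array_equal(out[f"resp_{b}"], out[f"true_{b}"])

    def test_direct_arm_rate_is_prevalence_times_report_rate(self):
        # theft: 0.8329 x 0.6918 ~ 0.5762 at large n
        cfg = default_config(n=100_000)
        # scale the default count marginals to probabilities for the larger n
        cfg.covariate_marginals = {
            cov: {lvl: cnt / 792 for lvl, cnt in marg.items()}
            for cov, marg in rs.cohort.DEFAULT_MARGINALS.items()
        }
        coh = assign_arms(generate_cohort(cfg, seed=21), 0.5, seed=22)
        out = apply_response_mechanism(coh, STUDY_DESIGN, seed=23)
        direct = out[out["arm"] == "direct"]
        expected = 0.8329 * DEFAULT_DQ_REPORT_RATES["theft"]
        assert abs(direct["resp_theft"].mean() - expected) < 0.01

    def test_indirect_arm_rate_matches_response_probability(self):
        n = 100_000
        truth = (np.random.default_rng(3).random(n) < 0.8329).astype(np.int8)
        coh = pd.DataFrame({"arm": "indirect", **{f"true_{b}": truth for b in BEHAVIOURS}})
        out = apply_response_mechanism(coh, STUDY_DESIGN, seed=31)
        lam = rs.response_probability(STUDY_DESIGN, truth.mean())
        assert abs(out["resp_theft"].mean() - lam) < 0.005

    def test_no_false_confessions_under_direct_questioning(self):
        coh = assign_arms(generate_cohort(seed=13), seed=14)
        out = apply_response_mechanism(coh, STUDY_DESIGN, seed=15)
        direct = out[out["arm"] == "direct"]
        for b in BEHAVIOURS:
            assert not ((direct[f"resp_{b}"] == 1) & (direct[f"true_{b}"] == 0)).any()

    def test_missing_latent_status_rejected(self):
        coh = assign_arms(generate_cohort(seed=1), seed=2).drop(columns=["true_arson"])
        with pytest.raises(ValueError, match="true_arson"):
            apply_response_mechanism(coh, STUDY_DESIGN)


class TestEndToEndRecovery:
    def test_indirect_arm_estimator_recovers_configured_prevalence(self):
        # 200 replications at the default n: the device-corrected estimate
        # should sit within 3 estimated SEs of the configured prevalence
        # in >= 99% of surveys
        hits = 0
        for i in range(200):
            coh = rs.simulate_survey(seed=50_000 + i)
            y = coh.loc[coh["arm"] == "indirect", "resp_theft"]
            est = rs.estimate_prevalence(y, STUDY_DESIGN)
            hits += abs(est.estimate_raw - 0.8329) <= 3 * np.sqrt(est.variance)
        assert hits / 200 >= 0.99

    def test_direct_arm_converges_to_underreported_rate(self):
        # the social-desirability gap: DQ estimates prevalence*report_rate
        rates = []
        for i in range(50):
            coh = rs.simulate_survey(seed=70_000 + i)
            y = coh.loc[coh["arm"] == "direct", "resp_theft"]
            rates.append(rs.estimate_prevalence(y, direct_design()).estimate)
        mean_rate = np.mean(rates)
        assert abs(mean_rate - 0.8329 * DEFAULT_DQ_REPORT_RATES["theft"]) < 0.015
        assert mean_rate < 0.8329 - 0.05
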