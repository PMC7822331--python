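import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rrsurvey as rs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_design():
    return rs.STUDY_DESIGN


@pytest.fixture(scope="session")
def survey_cohort():
    """One default synthetic two-arm survey, shared across tests."""
    return rs.simulate_survey(seed=2021)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_mixed_dataset():
    """Seeded 2,000-row two-arm dataset from a known latent logistic model.

    beta = (0.6 intercept, 2.3 on the arm indicator, 0.06 on a continuous
    severity-like covariate); rows carry (0,1) / (0.2,0.6) per arm.
    """
    rng = np.random.default_rng(99)
    n = 2000
    arm = np.where(rng.random(n) < 0.5, "indirect", "direct")
    oc = rng.normal(7.34, 7.121, n).clip(0, 40)
    indicator = (arm == "indirect").astype(float)
    eta = 0.6 + 2.3 * indicator + 0.06 * oc
    mu = 1.0 / (1.0 + np.exp(-eta))
    c = np.where(arm == "indirect", 0.2, 0.0)
    d = np.where(arm == "indirect", 0.6, 1.0)
    y = (rng.random(n) < c + d * mu).astype(int)
    X = np.column_stack([indicator, oc])
    return {"X": X, "y": y, "c": c, "d": d, "beta": np.array([0.6, 2.3, 0.06])}
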