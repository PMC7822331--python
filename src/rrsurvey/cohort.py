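"""Synthetic respondent cohorts for a two-arm sensitive-behaviour survey.

Generates prison-inmate-like cohorts with fixed categorical marginals
(education, marital status, nationality, crime, in-prison conduct),
truncated continuous covariates (age, sentence length, obsessive-compulsive
severity score), latent true statuses for five sensitive behaviours drawn
from a per-behaviour logistic model, random assignment to a direct- or
indirect-questioning arm, and observed answers produced either through the
randomizing device or through a one-sided under-reporting mechanism.

The defaults emulate the structure of a survey of 792 male inmates of a
Spanish prison questioned about theft, illicit drug use, violence against
property, reckless driving (speeding) and arson: categorical marginals and
continuous moments match the published sample description, latent
prevalences match the published indirect (forced-response) estimates, and
the direct-questioning report rates are calibrated so the direct arm
reproduces the published direct estimates in expectation.  Everything is
overridable through :class:`CohortConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .design import RRDesign, randomize_response

__all__ = [
    "BEHAVIOURS",
    "CATEGORICAL_LEVELS",
    "ARMS",
    "BehaviourModel",
    "CohortConfig",
    "generate_cohort",
    "assign_arms",
    "apply_response_mechanism",
    "simulate_survey",
    "default_config",
]

#: The five sensitive behaviours, in report order.
BEHAVIOURS = ("theft", "drugs", "violence", "speeding", "arson")

ARMS = ("direct", "indirect")

#: Category vocabularies for the categorical covariates.  The first level
#: of each is the regression reference class.
CATEGORICAL_LEVELS = {
    "education": ("none", "primary", "secondary", "higher"),
    "marital_status": ("single", "married", "divorced", "cohabiting"),
    "nationality": ("spanish", "other"),
    "crime": ("theft", "violence", "sex_crime", "homicide_murder", "other"),
    "conduct": ("model", "acceptable", "wrong"),
}

RESPONSE_COLUMNS = tuple(f"resp_{b}" for b in BEHAVIOURS)
TRUE_COLUMNS = tuple(f"true_{b}" for b in BEHAVIOURS)


@dataclass(frozen=True)
class BehaviourModel:
    """Latent-status model for one behaviour.

    ``prevalence`` is the target population prevalence; the logistic
    intercept is calibrated per cohort so the mean latent probability over
    the drawn covariates equals it exactly.  ``coef`` maps covariate terms
    to log-odds effects: categorical effects are keyed
    ``"covariate:level"`` (reference levels implicitly zero), numeric
    effects are keyed by column name (``age``, ``sentence_months``,
    ``oc_score``).
    """

    prevalence: float
    coef: dict = field(default_factory=dict)

    def linear_predictor(self, cohort: pd.DataFrame) -> np.ndarray:
        """Covariate part of the log-odds (no intercept)."""
        eta = np.zeros(len(cohort))
        for key, beta in self.coef.items():
            if ":" in key:
                cov, level = key.split(":", 1)
                eta += beta * (cohort[cov].to_numpy() == level)
            else:
                eta += beta * cohort[key].to_numpy(dtype=float)
        return eta


# Per-behaviour latent models.  Prevalences are the published indirect
# (device-corrected) estimates; covariate log-odds default to the published
# regression point estimates where a model was reported (theft, drugs,
# arson) and to zero otherwise.  The questioning-method effect is a
# reporting artefact, not a latent trait effect, so it never enters here.
DEFAULT_BEHAVIOUR_MODELS = {
    "theft": BehaviourModel(
        prevalence=0.8329,
        coef={
            "marital_status:married": -0.7398,
            "marital_status:divorced": -0.0104,
            "marital_status:cohabiting": 0.3850,
            "crime:violence": -1.7879,
            "crime:sex_crime": -3.0138,
            "crime:homicide_murder": -2.2686,
            "crime:other": -1.8188,
            "conduct:acceptable": 0.4243,
            "conduct:wrong": 1.9446,
            "sentence_months": 0.0065,
            "oc_score": 0.0585,
        },
    ),
    "drugs": BehaviourModel(
        prevalence=0.9983,
        coef={
            "marital_status:married": -0.4495,
            "marital_status:divorced": -0.7704,
            "marital_status:cohabiting": -0.5358,
            "education:primary": -0.4209,
            "education:secondary": -0.2257,
            "education:higher": -1.5319,
            "crime:violence": -0.7216,
            "crime:sex_crime": -1.5822,
            "crime:homicide_murder": -0.9157,
            "crime:other": -0.5373,
            "conduct:acceptable": 0.7571,
            "conduct:wrong": 1.6734,
            "oc_score": 0.0724,
        },
    ),
    "violence": BehaviourModel(prevalence=0.5867),
    "speeding": BehaviourModel(prevalence=0.9418),
    "arson": BehaviourModel(
        prevalence=0.2679,
        coef={
            "crime:violence": -0.8972,
            "crime:sex_crime": 0.9746,
            "crime:homicide_murder": -1.1933,
            "crime:other": 0.0095,
            "oc_score": 0.0673,
        },
    ),
}

# Published direct-arm estimates; the default per-behaviour probability
# that a true positive admits the behaviour under direct questioning is
# the ratio direct/indirect, so the direct arm reproduces the published
# direct rates in expectation (e.g. theft: 0.5762/0.8329 = 0.6918).
_DIRECT_ESTIMATES = {
    "theft": 0.5762,
    "drugs": 0.7021,
    "violence": 0.3002,
    "speeding": 0.7215,
    "arson": 0.0750,
}
DEFAULT_DQ_REPORT_RATES = {
    b: _DIRECT_ESTIMATES[b] / DEFAULT_BEHAVIOUR_MODELS[b].prevalence
    for b in BEHAVIOURS
}

# Sample-description categorical counts for n = 792.  The published
# marital-status and crime columns sum to 790; the two unaccounted
# records are assigned to the modal category (single / other).
DEFAULT_MARGINALS = {
    "education": {"none": 125, "primary": 377, "secondary": 207, "higher": 83},
    "marital_status": {"single": 378, "married": 160, "divorced": 113, "cohabiting": 141},
    "nationality": {"spanish": 747, "other": 45},
    "crime": {
        "theft": 335,
        "violence": 119,
        "sex_crime": 52,
        "homicide_murder": 49,
        "other": 237,
    },
    "conduct": {"model": 449, "acceptable": 301, "wrong": 42},
}


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort.

    Categorical marginals may be integer counts (must sum to ``n``; the
    cohort then matches them exactly) or probabilities (must sum to 1;
    categories are then sampled independently).
    """

    n: int = 792
    arm_split: float = 0.5  # proportion assigned to the indirect arm
    covariate_marginals: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    age_mean: float = 37.01
    age_sd: float = 9.317
    age_bounds: tuple = (18.0, 55.0)
    sentence_mean: float = 69.76  # months
    sentence_sd: float = 72.626
    oc_mean: float = 7.34  # 0-40 severity score
    oc_sd: float = 7.121
    behaviour_model: dict = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOUR_MODELS)
    )
    dq_report_rate: dict = field(
        default_factory=lambda: dict(DEFAULT_DQ_REPORT_RATES)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not 0.0 < self.arm_split < 1.0:
            raise ValueError("arm_split must lie strictly between 0 and 1")
        for cov, marg in self.covariate_marginals.items():
            if cov not in CATEGORICAL_LEVELS:
                raise ValueError(f"unknown covariate {cov!r}")
            unknown = set(marg) - set(CATEGORICAL_LEVELS[cov])
            if unknown:
                raise ValueError(
                    f"unknown categories {sorted(unknown)} for covariate {cov!r}"
                )
            total = sum(marg.values())
            if all(float(v).is_integer() for v in marg.values()) and total > 1:
                if self.n and total != self.n:
                    raise ValueError(
                        f"count marginals for {cov!r} sum to {total}, expected n={self.n}"
                    )
            elif abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"probability marginals for {cov!r} sum to {total}, expected 1"
                )
        for b, rate in self.dq_report_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"dq_report_rate[{b!r}]={rate} outside [0, 1]")
        for b, model in self.behaviour_model.items():
            if not 0.0 < model.prevalence < 1.0:
                raise ValueError(
                    f"behaviour_model[{b!r}].prevalence must lie in (0, 1)"
                )


def default_config(**overrides) -> CohortConfig:
    """A fresh default configuration with optional field overrides.

    When ``n`` differs from the default 792 and no explicit marginals are
    given, the default count marginals are rescaled to probabilities so
    any cohort size remains valid.
    """
    cfg = replace(CohortConfig(), **overrides)
    if cfg.n != 792 and "covariate_marginals" not in overrides:
        cfg.covariate_marginals = {
            cov: {lvl: cnt / 792 for lvl, cnt in marg.items()}
            for cov, marg in DEFAULT_MARGINALS.items()
        }
    return cfg


def _sample_categorical(marginal: dict, levels, n: int, rng) -> np.ndarray:
    values = list(marginal.values())
    if all(float(v).is_integer() for v in values) and sum(values) > 1:
        # exact counts: permute the implied multiset
        pool = np.repeat(
            [lvl for lvl in levels if lvl in marginal],
            [int(marginal[lvl]) for lvl in levels if lvl in marginal],
        )
        return rng.permutation(pool)
    probs = np.array([marginal.get(lvl, 0.0) for lvl in levels], dtype=float)
    return rng.choice(np.array(levels, dtype=object), size=n, p=probs / probs.sum())


def _truncated_normal(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _lognormal_matched(mean, sd, size, rng):
    """Log-normal draws with the given arithmetic mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def calibrate_intercept(model: BehaviourModel, cohort: pd.DataFrame) -> float:
    """Intercept making the cohort-mean latent probability equal the target.

    Solves mean(expit(b0 + eta_i)) = prevalence by bracketed root finding;
    the mean is strictly increasing in b0 so the root is unique.
    """
    eta = model.linear_predictor(cohort)
    target = model.prevalence

    def gap(b0):
        return expit(b0 + eta).mean() - target

    return brentq(gap, -40.0, 40.0, xtol=1e-12)


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort of respondents with covariates and latent statuses.

    Categorical covariates are sampled independently of one another;
    latent statuses are independent across behaviours given covariates.
    Deterministic given the seed (``seed`` argument overrides
    ``config.seed``).

    Returns a DataFrame with columns ``id``, the five categorical and
    three numeric covariates, and ``true_<behaviour>`` latent statuses.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n

    if n == 0:
        empty: dict = {"id": np.array([], dtype=int)}
        for cov in CATEGORICAL_LEVELS:
            empty[cov] = np.array([], dtype=object)
        for num in ("age", "sentence_months"):
            empty[num] = np.array([], dtype=float)
        empty["oc_score"] = np.array([], dtype=int)
        for b in BEHAVIOURS:
            empty[f"true_{b}"] = np.array([], dtype=np.int8)
        return pd.DataFrame(empty)

    cols: dict = {"id": np.arange(n)}
    for cov, levels in CATEGORICAL_LEVELS.items():
        marginal = config.covariate_marginals.get(cov)
        if marginal is None:
            raise ValueError(f"missing marginal for covariate {cov!r}")
        cols[cov] = _sample_categorical(marginal, levels, n, rng)

    lo, hi = config.age_bounds
    cols["age"] = _truncated_normal(config.age_mean, config.age_sd, lo, hi, n, rng)
    cols["sentence_months"] = _lognormal_matched(
        config.sentence_mean, config.sentence_sd, n, rng
    )
    oc = _truncated_normal(config.oc_mean, config.oc_sd, 0.0, 40.0, n, rng)
    cols["oc_score"] = np.rint(oc).astype(int)

    cohort = pd.DataFrame(cols)

    for b in BEHAVIOURS:
        model = config.behaviour_model[b]
        b0 = calibrate_intercept(model, cohort)
        p = expit(b0 + model.linear_predictor(cohort))
        cohort[f"true_{b}"] = (rng.random(n) < p).astype(np.int8)

    return cohort


def assign_arms(cohort: pd.DataFrame, arm_split: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Randomly assign respondents to the direct or indirect arm.

    The indirect arm receives ``round(n * arm_split)`` respondents
    (banker's rounding via numpy, so an odd n at split 0.5 puts the extra
    respondent in the direct arm).  Assignment is a seeded uniform
    permutation of row positions, so reordering rows while keeping the
    seed changes which respondents land where.
    """
    if not 0.0 < arm_split < 1.0:
        raise ValueError("arm_split must lie strictly between 0 and 1")
    n = len(cohort)
    n_indirect = int(np.rint(n * arm_split))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    arm = np.full(n, "direct", dtype=object)
    arm[order[:n_indirect]] = "indirect"
    out = cohort.copy()
    out["arm"] = arm
    return out


def apply_response_mechanism(
    cohort: pd.DataFrame,
    design: RRDesign,
    dq_report_rate: dict | float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Produce observed answers from latent statuses.

    Indirect-arm answers pass through the randomizing device.  Direct-arm
    answers follow a one-sided under-reporting model: a true positive
    admits the behaviour with probability ``dq_report_rate[behaviour]``,
    a true negative never falsely confesses.

    Requires ``arm`` and all ``true_*`` columns.
    """
    if "arm" not in cohort.columns:
        raise ValueError("cohort has no 'arm' column; run assign_arms first")
    missing = [c for c in TRUE_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks latent status columns: {missing}")

    if dq_report_rate is None:
        dq_report_rate = dict(DEFAULT_DQ_REPORT_RATES)
    if np.isscalar(dq_report_rate):
        dq_report_rate = {b: float(dq_report_rate) for b in BEHAVIOURS}

    rng = np.random.default_rng(seed)
    out = cohort.copy()
    indirect = (out["arm"] == "indirect").to_numpy()
    for b in BEHAVIOURS:
        true = out[f"true_{b}"].to_numpy()
        observed = np.empty(len(out), dtype=np.int8)
        # device arm: draws with replacement, independent across items
        observed[indirect] = randomize_response(true[indirect], design, rng)
        rate = dq_report_rate[b]
        direct_true = true[~indirect]
        observed[~indirect] = direct_true * (
            rng.random(direct_true.shape) < rate
        ).astype(np.int8)
        out[f"resp_{b}"] = observed
    return out


def simulate_survey(
    config: CohortConfig | None = None,
    design: RRDesign | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full synthetic survey: generate covariates/latents, assign arms,
    apply the response mechanisms.

    A single master seed deterministically spawns independent substreams
    for the three stages, so re-running any stage alone reproduces its
    draws.
    """
    from .design import STUDY_DESIGN

    config = config or CohortConfig()
    design = design or STUDY_DESIGN
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    s_cohort, s_arms, s_resp = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    cohort = generate_cohort(config, seed=s_cohort)
    cohort = assign_arms(cohort, config.arm_split, seed=s_arms)
    return apply_response_mechanism(cohort, design, config.dq_report_rate, seed=s_resp)
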