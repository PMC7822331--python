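"""Monte Carlo evaluation of the survey estimators.

Frequentist operating characteristics — interval coverage, estimator
bias, and type-I error / power of the two-arm contrast — computed by
repeated simulation of surveys through the package's own estimators.
Respondent-level answers are Bernoulli with the device-implied success
probability, so per-survey yes-counts are drawn as binomials (the exact
sufficient statistic for the equal-weight estimator), which keeps large
replication counts cheap without changing the sampling distribution.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .design import RRDesign, response_probability

__all__ = [
    "simulate_frd_estimates",
    "interval_coverage",
    "estimator_mean",
    "two_arm_rejection_rate",
]


def _survey_estimates(design: RRDesign, lam_true: float, n: int, reps: int, rng):
    """Untruncated estimates and variance estimates for `reps` surveys."""
    yes = rng.binomial(n, lam_true, size=reps)
    lam_hat = yes / n
    est_raw = (lam_hat - design.c) / design.d
    variance = lam_hat * (1.0 - lam_hat) / (n - 1) / design.d**2
    return est_raw, variance


def simulate_frd_estimates(
    design: RRDesign, pi: float, n: int, reps: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate `reps` surveys of size `n` at true prevalence `pi`.

    True statuses are latent Bernoulli(pi); answers pass through the
    device, so observed yes-counts are Binomial(n, c + d*pi).  Returns
    (untruncated estimates, variance estimates).
    """
    rng = np.random.default_rng(seed)
    lam = response_probability(design, pi)
    return _survey_estimates(design, lam, n, reps, rng)


def interval_coverage(
    design: RRDesign,
    pi: float,
    n: int,
    reps: int,
    level: float = 0.95,
    seed: int = 0,
) -> float:
    """Empirical coverage of the truncated Wald interval.

    Fraction of simulated surveys whose nominal-`level` interval contains
    the true prevalence.  Truncation to [0, 1] never excludes a true
    prevalence inside [0, 1], so coverage is computed on the truncated
    interval the package reports.
    """
    est_raw, variance = simulate_frd_estimates(design, pi, n, reps, seed)
    z = stats.norm.ppf((1.0 + level) / 2.0)
    half = z * np.sqrt(variance)
    lo = np.clip(est_raw - half, 0.0, 1.0)
    hi = np.clip(est_raw + half, 0.0, 1.0)
    return float(np.mean((lo <= pi) & (pi <= hi)))


def estimator_mean(design: RRDesign, pi: float, n: int, reps: int, seed: int = 0) -> float:
    """Monte Carlo mean of the untruncated estimator (bias check)."""
    est_raw, _ = simulate_frd_estimates(design, pi, n, reps, seed)
    return float(est_raw.mean())


def two_arm_rejection_rate(
    design: RRDesign,
    pi: float,
    dq_report_rate: float,
    n_direct: int,
    n_indirect: int,
    alpha: float,
    reps: int,
    seed: int = 0,
) -> float:
    """Rejection rate of the two-sided direct-vs-indirect z test.

    Direct-arm answers are Bernoulli(pi * dq_report_rate) — true
    positives admit with probability `dq_report_rate`, true negatives
    never falsely confess; indirect-arm answers pass through the device.
    With `dq_report_rate = 1` both arms estimate the same prevalence and
    the rate is the empirical type-I error; with under-reporting it is
    power.
    """
    rng = np.random.default_rng(seed)
    from .design import direct_design

    dq = direct_design()
    est_dq, var_dq = _survey_estimates(dq, pi * dq_report_rate, n_direct, reps, rng)
    lam_rr = response_probability(design, pi)
    est_rr, var_rr = _survey_estimates(design, lam_rr, n_indirect, reps, rng)
    z = (est_rr - est_dq) / np.sqrt(var_rr + var_dq)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return float(np.mean(p < alpha))
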