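"""Design-corrected prevalence estimation for randomized-response surveys.

The device maps the true prevalence ``pi`` to the observed "yes"
probability ``lambda = c + d * pi``; the design-based (Horvitz-Thompson
type) estimator inverts this line:

    pi_hat = (lambda_hat - c) / d,
    V(pi_hat) = V(lambda_hat) / d**2,

with ``lambda_hat`` the (weighted) observed yes-proportion.  Under equal
weights the variance estimate is the simple-random-sampling form
``lambda_hat * (1 - lambda_hat) / (n - 1)`` without finite-population
correction; under unequal weights the standard ratio-estimator
approximation is used, which reduces to the same expression when weights
are equal.  Confidence intervals are Wald intervals on the untruncated
estimate, truncated afterwards to the probability scale [0, 1] — the
untruncated estimate is preserved for diagnostics (and is the quantity
the two-arm comparison test operates on).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .cohort import ARMS, BEHAVIOURS, CATEGORICAL_LEVELS
from .design import RRDesign, direct_design

__all__ = [
    "PrevalenceEstimate",
    "ForcedResponsePrevalence",
    "estimate_prevalence",
    "truncated_wald_ci",
    "subgroup_estimates",
    "prevalence_table",
]


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A design-corrected prevalence with its uncertainty.

    ``estimate`` is truncated to [0, 1]; ``estimate_raw`` is the
    untruncated inversion ``(lambda_hat - c) / d``.  ``variance`` is None
    for flagged degenerate cells (n < 2), in which case the interval
    bounds are None too.
    """

    behaviour: str | None
    arm: str | None
    n: int
    observed_rate: float
    estimate: float
    estimate_raw: float
    variance: float | None
    ci_low: float | None
    ci_high: float | None
    level: float
    subgroup: str | None = None

    @property
    def degenerate(self) -> bool:
        return self.variance is None


def truncated_wald_ci(estimate: float, variance: float, level: float = 0.95):
    """Wald interval ``estimate +/- z * sqrt(variance)`` truncated to [0, 1].

    Operates on the untruncated estimate; truncation happens last, which
    is what produces printed upper bounds of exactly 1.0000 for
    behaviours whose corrected estimate sits near the boundary.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf((1.0 + level) / 2.0)
    half = z * np.sqrt(variance)
    return max(0.0, estimate - half), min(1.0, estimate + half)


class ForcedResponsePrevalence(BaseEstimator):
    """Prevalence estimator for binary answers observed through a
    forced-response device.

    Parameters
    ----------
    design : RRDesign, optional
        The randomizing device; defaults to direct questioning
        ``(c, d) = (0, 1)``, under which the estimator reduces to the
        (weighted) sample proportion.
    level : float, default 0.95
        Confidence level for the truncated Wald interval.

    Attributes (after :meth:`fit`)
    ------------------------------
    n_ : int
    observed_rate_ : float          weighted yes-proportion ``lambda_hat``
    estimate_raw_ : float           untruncated ``(lambda_hat - c) / d``
    estimate_ : float               truncated to [0, 1]
    variance_ : float
    ci_low_, ci_high_ : float       truncated Wald bounds
    """

    def __init__(self, design: RRDesign | None = None, level: float = 0.95):
        self.design = design
        self.level = level

    def fit(self, y, sample_weight=None):
        design = self.design if self.design is not None else direct_design()
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if n < 2:
            raise ValueError("need at least 2 responses (variance undefined)")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("responses must be binary (0/1)")
        if sample_weight is None:
            w = np.ones(n)
        else:
            w = np.asarray(sample_weight, dtype=float).ravel()
            if w.shape != y.shape:
                raise ValueError("sample_weight length mismatch")
            if np.any(w <= 0):
                raise ValueError("sampling weights must be strictly positive")

        wsum = w.sum()
        lam = float(np.sum(w * y) / wsum)
        # ratio-estimator variance of the weighted mean; equals
        # lam*(1-lam)/(n-1) when weights are equal
        v_lam = float(np.sum(w**2 * (y - lam) ** 2) / wsum**2 * n / (n - 1))

        self.n_ = n
        self.observed_rate_ = lam
        self.estimate_raw_ = (lam - design.c) / design.d
        self.estimate_ = float(np.clip(self.estimate_raw_, 0.0, 1.0))
        self.variance_ = v_lam / design.d**2
        self.ci_low_, self.ci_high_ = truncated_wald_ci(
            self.estimate_raw_, self.variance_, self.level
        )
        return self

    def to_result(self, behaviour=None, arm=None, subgroup=None) -> PrevalenceEstimate:
        return PrevalenceEstimate(
            behaviour=behaviour,
            arm=arm,
            subgroup=subgroup,
            n=self.n_,
            observed_rate=self.observed_rate_,
            estimate=self.estimate_,
            estimate_raw=self.estimate_raw_,
            variance=self.variance_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            level=self.level,
        )


def estimate_prevalence(
    responses,
    design: RRDesign | None = None,
    weights=None,
    level: float = 0.95,
    behaviour: str | None = None,
    arm: str | None = None,
    subgroup: str | None = None,
) -> PrevalenceEstimate:
    """Functional wrapper around :class:`ForcedResponsePrevalence`."""
    est = ForcedResponsePrevalence(design=design, level=level).fit(
        responses, sample_weight=weights
    )
    return est.to_result(behaviour=behaviour, arm=arm, subgroup=subgroup)


def _degenerate_estimate(y, design, level, **tags) -> PrevalenceEstimate:
    n = len(y)
    lam = float(np.mean(y)) if n else float("nan")
    raw = (lam - design.c) / design.d if n else float("nan")
    return PrevalenceEstimate(
        n=n,
        observed_rate=lam,
        estimate=float(np.clip(raw, 0, 1)) if n else float("nan"),
        estimate_raw=raw,
        variance=None,
        ci_low=None,
        ci_high=None,
        level=level,
        **tags,
    )


def _designs_per_arm(designs) -> dict:
    if isinstance(designs, RRDesign):
        return {"direct": direct_design(), "indirect": designs}
    return dict(designs)


def subgroup_estimates(
    cohort: pd.DataFrame,
    behaviour: str,
    covariate: str,
    designs,
    level: float = 0.95,
) -> list[PrevalenceEstimate]:
    """Per-category, per-arm prevalence estimates for one behaviour.

    ``designs`` is either a mapping arm -> RRDesign, or the indirect-arm
    design alone (the direct arm then uses the degenerate design).
    Categories with fewer than 2 respondents in an arm are emitted with a
    flagged absent variance rather than dropped, so subgroup counts always
    partition the arm.
    """
    if covariate not in CATEGORICAL_LEVELS:
        raise ValueError(
            f"unknown covariate {covariate!r}; expected one of {sorted(CATEGORICAL_LEVELS)}"
        )
    designs = _designs_per_arm(designs)
    col = f"resp_{behaviour}"
    if col not in cohort.columns:
        raise ValueError(f"behaviour {behaviour!r} absent from cohort")
    out = []
    for arm in ARMS:
        arm_rows = cohort[cohort["arm"] == arm]
        for category in CATEGORICAL_LEVELS[covariate]:
            rows = arm_rows[arm_rows[covariate] == category]
            tag = f"{covariate}={category}"
            y = rows[col].to_numpy()
            if len(y) < 2:
                out.append(
                    _degenerate_estimate(
                        y, designs[arm], level,
                        behaviour=behaviour, arm=arm, subgroup=tag,
                    )
                )
            else:
                out.append(
                    estimate_prevalence(
                        y, designs[arm], level=level,
                        behaviour=behaviour, arm=arm, subgroup=tag,
                    )
                )
    return out


def prevalence_table(
    cohort: pd.DataFrame,
    designs,
    behaviours=BEHAVIOURS,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-behaviour, per-arm estimates as a tidy report table.

    One row per (behaviour, arm) in fixed behaviour order with columns
    behaviour, method, n, estimate, variance, lower and upper bounds.
    """
    designs = _designs_per_arm(designs)
    rows = []
    for b in behaviours:
        col = f"resp_{b}"
        if col not in cohort.columns:
            continue
        for arm in ARMS:
            y = cohort.loc[cohort["arm"] == arm, col].to_numpy()
            est = estimate_prevalence(y, designs[arm], level=level, behaviour=b, arm=arm)
            rows.append(
                {
                    "behaviour": b,
                    "method": arm,
                    "n": est.n,
                    "estimate": est.estimate,
                    "variance": est.variance,
                    "lower": est.ci_low,
                    "upper": est.ci_high,
                }
            )
    return pd.DataFrame(rows)
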