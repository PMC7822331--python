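"""Direct-vs-indirect contrasts: the social-desirability-bias signal.

If respondents under-report a stigmatized behaviour when questioned
directly, the device-corrected indirect estimate exceeds the direct one.
The contrast is tested with a two-sided z statistic on the difference of
the untruncated estimates, with independent-arm variances summed:

    z = (pi_hat_RR - pi_hat_DQ) / sqrt(V_RR + V_DQ).

Effect size is Cohen's h, the arcsine-transformed difference of two
proportions — the standard effect measure when both quantities are
probabilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ARMS, BEHAVIOURS
from .prevalence import PrevalenceEstimate, _designs_per_arm, estimate_prevalence

__all__ = ["ComparisonResult", "compare_methods", "cohens_h", "compare_all"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonResult:
    behaviour: str | None
    z: float
    p_value: float
    effect_size_h: float
    direction: int  # sign of (indirect - direct)


def cohens_h(p_a: float, p_b: float) -> float:
    """Cohen's h effect size, ``2*(arcsin(sqrt(p_b)) - arcsin(sqrt(p_a)))``.

    Antisymmetric in its arguments; inputs are truncated probabilities.
    """
    for p in (p_a, p_b):
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0, 1]")
    return float(2.0 * (np.arcsin(np.sqrt(p_b)) - np.arcsin(np.sqrt(p_a))))


def compare_methods(
    direct: PrevalenceEstimate, indirect: PrevalenceEstimate
) -> ComparisonResult:
    """Two-sided z test of indirect minus direct prevalence.

    Uses the untruncated estimates (the truncation is a reporting device;
    the test statistic needs the raw scale) and treats the arms as
    independent samples.
    """
    if direct.behaviour != indirect.behaviour:
        raise ValueError(
            f"estimates describe different behaviours: "
            f"{direct.behaviour!r} vs {indirect.behaviour!r}"
        )
    if direct.variance is None or indirect.variance is None:
        raise ValueError("both estimates must carry variances")
    v = direct.variance + indirect.variance
    if v == 0:
        raise ValueError("both variances are zero; test undefined")
    diff = indirect.estimate_raw - direct.estimate_raw
    z = diff / np.sqrt(v)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(
        behaviour=direct.behaviour,
        z=float(z),
        p_value=p,
        effect_size_h=cohens_h(direct.estimate, indirect.estimate),
        direction=int(np.sign(diff)),
    )


def compare_all(
    cohort: pd.DataFrame,
    designs,
    behaviours=BEHAVIOURS,
    level: float = 0.95,
) -> pd.DataFrame:
    """Full per-behaviour report: both arms' estimates plus the contrast.

    Two rows per behaviour (direct then indirect) in fixed behaviour
    order; the p-value and effect size are carried on the direct row of
    each pair.  Behaviours absent from the data are omitted with a logged
    warning.
    """
    designs = _designs_per_arm(designs)
    for arm in ARMS:
        if (cohort["arm"] == arm).sum() == 0:
            raise ValueError(f"cohort has no respondents in the {arm!r} arm")
    rows = []
    for b in behaviours:
        col = f"resp_{b}"
        if col not in cohort.columns:
            msg = f"behaviour {b!r} absent from the data; row omitted"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        per_arm = {}
        for arm in ARMS:
            y = cohort.loc[cohort["arm"] == arm, col].to_numpy()
            per_arm[arm] = estimate_prevalence(
                y, designs[arm], level=level, behaviour=b, arm=arm
            )
        contrast = compare_methods(per_arm["direct"], per_arm["indirect"])
        for arm in ARMS:
            est = per_arm[arm]
            first = arm == "direct"
            rows.append(
                {
                    "behaviour": b,
                    "method": arm,
                    "n": est.n,
                    "estimate": est.estimate,
                    "variance": est.variance,
                    "lower": est.ci_low,
                    "upper": est.ci_high,
                    "p_value": contrast.p_value if first else np.nan,
                    "effect_size_h": contrast.effect_size_h if first else np.nan,
                }
            )
    return pd.DataFrame(rows)
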