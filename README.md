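# rrsurvey

Analysis tools for **randomized-response surveys** of sensitive behaviours:
design-based prevalence estimation, direct-vs-indirect comparison, and a
misclassification-adjusted logistic regression, together with a synthetic
two-arm cohort generator that makes the whole pipeline testable end to end.

## The problem

Self-reports of stigmatized behaviour (theft, drug use, violence, reckless
driving, arson, ...) suffer from *social desirability bias*: respondents
withhold admissions when questioned directly, so naive prevalence estimates
are biased downwards. The **forced response design** (FRD) is a classic
randomized-response remedy: each respondent draws a card from a deck in
private; with probability `p1` the card forces the answer "yes", with
probability `p2` it forces "no", and with probability `p3 = 1 − p1 − p2` it
requests the genuine answer. No individual answer reveals the respondent's
status, yet the device induces a known affine *misclassification line*

```
λ = c + d·π ,        c = p1 ,  d = p3 ,
```

between the true prevalence π and the observed yes-probability λ. The
package is built around this line:

- **Prevalence** (`ForcedResponsePrevalence`): the design-based estimator
  `π̂ = (λ̂ − c)/d` with variance `λ̂(1−λ̂)/((n−1)·d²)` (SRS form, no fpc;
  generic positive weights supported) and a Wald interval truncated to
  [0, 1]. Direct questioning is the degenerate design `(c, d) = (0, 1)`.
- **Comparison** (`compare_methods`, `compare_all`): two-sided z test of
  the indirect-minus-direct gap on the untruncated estimates, with Cohen's
  *h* (`2·(arcsin√p₂ − arcsin√p₁)`) as the effect size.
- **Regression** (`RRLogisticRegression`, `fit_rr_model`,
  `stepwise_select`): maximum-likelihood logistic regression in which each
  row carries its own `(cᵢ, dᵢ)` so both survey arms enter one joint fit,

  ```
  ℓ(β) = Σᵢ yᵢ·log(cᵢ + dᵢ·μᵢ) + (1−yᵢ)·log(1 − cᵢ − dᵢ·μᵢ),   μᵢ = expit(xᵢᵀβ),
  ```

  fitted by Newton's method with Wald inference, AIC-based bidirectional
  stepwise selection (categorical blocks move whole; the questioning-method
  term is never dropped), and a Pearson goodness-of-fit statistic on the
  observed-response scale.
- **Synthetic cohorts** (`simulate_survey`): two-arm respondent cohorts
  emulating a survey of 792 male Spanish prison inmates — exact categorical
  marginals, truncated continuous covariates, latent statuses from a
  calibrated logistic model, and a one-sided under-reporting mechanism in
  the direct arm.

The default device is the 40-card Spanish deck used in that survey
(8 forced-yes, 8 forced-no, 24 genuine cards), giving `(c, d) = (0.2, 0.6)`.

## Worked example

```python
import rrsurvey as rs

cohort = rs.simulate_survey(seed=7)          # 792 respondents, 396 per arm
report = rs.compare_all(cohort, rs.STUDY_DESIGN)
print(report.round(4).to_string(index=False))
```

```
behaviour   method   n  estimate  variance  lower  upper  p_value  effect_size_h
    theft   direct 396    0.4874    0.0006 0.4381 0.5367      0.0         0.7194
    theft indirect 396    0.8199    0.0015 0.7440 0.8958      NaN            NaN
    drugs   direct 396    0.7172    0.0005 0.6728 0.7616      0.0         0.6347
    drugs indirect 396    0.9419    0.0013 0.8722 1.0000      NaN            NaN
 violence   direct 396    0.2904    0.0005 0.2456 0.3352      0.0         0.8302
 violence indirect 396    0.6936    0.0017 0.6137 0.7735      NaN            NaN
 speeding   direct 396    0.7197    0.0005 0.6754 0.7640      0.0         0.5004
 speeding indirect 396    0.9082    0.0013 0.8366 0.9799      NaN            NaN
    arson   direct 396    0.0530    0.0001 0.0309 0.0751      0.0         0.6530
    arson indirect 396    0.2811    0.0016 0.2018 0.3604      NaN            NaN
```

Every indirect (device-corrected) estimate exceeds its direct counterpart
and every contrast is significant — the simulated respondents admit far
more through the device than under direct questioning, which is exactly
the under-reporting the generator builds in. Note the drugs upper bound of
1.0000: the Wald interval is computed on the raw estimate and truncated to
the probability scale. A regression on the same cohort:

```python
fit = rs.stepwise_select(
    cohort, "theft",
    ["method", "education", "marital_status", "crime", "conduct",
     "age", "sentence_months", "oc_score"],
)
print(rs.odds_ratio_table(fit).head(3).to_string(index=False))
print(f"AIC {fit.aic:.2f}  Pearson p {fit.pearson_p:.4f}")
```

```
            term estimate std_error exp_estimate p_value
     (Intercept)  -0.5745    0.4844       0.5630  0.2356
method[indirect]   1.6359    0.2889       5.1342  0.0000
...
AIC 1010.04  Pearson p 0.3555
```

`exp_estimate` is the odds ratio: respondents questioned through the
device have about 5× the odds of admitting theft, the residual reporting
gap after covariate adjustment.

The same pipeline is available from the shell:

```bash
rrsurvey all --seed 7 --out results/
```

which writes `cohort.csv`, `cohort_summary.csv`, `prevalence.csv`,
`comparison.csv` and per-behaviour `regression_*.csv` reports.

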