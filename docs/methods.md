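# Methods

## The forced-response model

A forced response design offers each respondent a randomizing device with
three outcomes: forced "yes" (probability `p1`), forced "no" (`p2`), and
"answer genuinely" (`p3 = 1 − p1 − p2 > 0`). Draws are independent with
replacement — the card is returned to the deck between questions — so each
observed answer is Bernoulli with success probability

```
λ = c + d·π,    c = p1,  d = p3.
```

The package stores the probability triple but exposes only the `(c, d)`
line to estimation and regression. Two parametrizations of this line
circulate in the randomized-response literature — one in terms of the deck
proportions directly, and one (used by misclassification-GLM software) in
terms of the genuine-answer probability and the forced-yes probability
*given* a forced answer, `c = (1 − p_genuine)·P(yes | forced)`,
`d = p_genuine`. For any forced-response device the two coincide, e.g. the
default 40-card deck gives `(0.2, 0.2, 0.6)` either way, hence
`(c, d) = (0.2, 0.6)`. Direct questioning is the degenerate design
`(0, 0, 1)`, i.e. `(c, d) = (0, 1)`; representing it this way lets one code
path serve both survey arms.

Respondents are assumed fully compliant with the device (no cheating
parameter), and the direct-questioning lying model is one-sided: a true
positive admits the behaviour with probability `dq_report_rate`, a true
negative never falsely confesses. Both assumptions match the
interpretation of an indirect-minus-direct gap as withheld admissions.

## Prevalence estimation

With observed answers `y_i` and positive weights `w_i` (all equal by
default; the estimator family is design-based, reducing to the sample mean
under equal weights):

- `λ̂ = Σ w_i y_i / Σ w_i`,
- `π̂_raw = (λ̂ − c)/d`, reported truncated to [0, 1] with the raw value
  preserved for diagnostics and testing,
- `V̂(π̂) = V̂(λ̂)/d²` with `V̂(λ̂) = λ̂(1−λ̂)/(n−1)` under equal weights
  (simple-random-sampling form, no finite-population correction); under
  unequal weights the ratio-estimator approximation
  `Σ w_i²(y_i−λ̂)² / (Σ w_i)² · n/(n−1)`, which reduces to the former when
  weights are equal. Reports label these variances design-based
  (SRS, no fpc); complex designs (stratification, clustering, calibration)
  are out of scope.
- Confidence interval: Wald, `π̂_raw ± z_{(1+level)/2}·√V̂`, truncated to
  [0, 1] *after* construction. Truncation (rather than a logit-scale
  interval) is deliberate: corrected estimates near the boundary should
  print bounds of exactly 1.0000, and the raw interval is the one with the
  standard coverage guarantee. Empirical coverage at the default design
  (n = 396, π = 0.58) is 95.2–95.3% over 5,000 replications.

The `1/d²` factor is the privacy premium: at equal n the device estimator's
variance always exceeds the direct estimator's (asserted from the closed
forms over a prevalence grid in the tests).

Subgroup estimates are computed per (category × arm) cell; cells with
fewer than two respondents are emitted with a flagged absent variance
rather than dropped, so cell counts always partition the arm.

## Two-arm comparison

`z = (π̂_RR − π̂_DQ)/√(V̂_RR + V̂_DQ)` on the *untruncated* estimates with
independent-arm variances, two-sided normal p-value. The choice of test is
an assumption of this package (a plain large-sample z test is the natural
one for two independent design-based estimates). Effect size is Cohen's
h = `2·(arcsin√p₂ − arcsin√p₁)` on the truncated estimates — the standard
effect measure for a difference of proportions. No multiple-testing
correction is applied across behaviours.

Monte Carlo operating characteristics under the default study conditions
(computed by `rrsurvey.simulation`, re-run in the test suite): type-I
error 5.1% at α = 0.05 (5,000 replications with full direct-arm
reporting); power of the theft contrast at α = 0.001 is ≈ 0.99
(analytically, mean z ≈ 5.6 against the 3.29 critical value; the test
suite asserts ≥ 0.97 to leave Monte Carlo slack). The arson contrast is
the weakest of the five (mean z ≈ 4.6, power ≈ 0.9 at α = 0.001) because
its prevalence gap is smallest relative to its noise.

## Misclassified-response logistic regression

Latent model `μ_i = expit(x_iᵀβ)`; observed-response likelihood

```
ℓ(β) = Σ_i  y_i·log(c_i + d_i μ_i) + (1−y_i)·log(1 − c_i − d_i μ_i).
```

Both arms enter one joint fit, each row carrying its own `(c_i, d_i)`,
with the questioning method also present as a covariate; this is the only
arrangement in which a "method" coefficient — the residual reporting gap
after covariate adjustment — is estimable.

Numerical choices:

- `μ` is clipped to `[1e-12, 1 − 1e-12]`, so the likelihood and gradient
  are finite for every finite β even on boundary rows (`c_i = 0`).
- Optimizer: Newton with backtracking Armijo line search from `β = 0`,
  with an absolute slack of `1e-10·(1+|ℓ|)` in the acceptance condition so
  full Newton steps remain acceptable at float precision near the optimum;
  BFGS (analytic gradient) as fallback whenever the Hessian step is not an
  ascent direction. Convergence: gradient max-norm < 1e-8.
- Standard errors from the inverse observed information at the optimum;
  Wald z and two-sided normal p-values per coefficient; odds ratios
  `exp(β)`; `AIC = 2k − 2ℓ`.
- Rank-deficient design matrices raise an error naming the collinear
  columns (small QR diagonal); non-convergence returns the fit flagged
  `converged = False` rather than raising.
- Categorical covariates are dummy-coded against fixed reference classes
  (direct questioning, no formal qualifications, single, theft, model
  conduct). Recoding the reference changes coefficients but not fitted
  probabilities (tested to 1e-10).

Stepwise selection is bidirectional on AIC from the full model; at each
step all single-term removals and additions are scored, categorical blocks
move whole, and the method term is never dropped (it is the design
variable of interest). A pure-noise 1-df term is dropped with probability
`P(χ²₁ < 2) ≈ 0.84` — the test suite measures 0.82 over 500 replications.

Goodness of fit is the Pearson statistic on the observed-response scale,
`X² = Σ (y_i − p*_i)²/(p*_i(1 − p*_i))` with `p*_i = c_i + d_i μ̂_i`,
referred to χ² with `n − k` degrees of freedom. For *ungrouped* binary
data this reference is known to be approximate: each term has mean 1 but
variance below 2 near `p* = 0.5`, so the statistic concentrates around its
degrees of freedom and the p-value is conservative (it clusters near 0.5
and essentially never rejects a well-specified model). It is reported as a
sanity check, not a calibrated test; the tests assert the conservative
direction (no spurious rejections) rather than uniformity.

## The synthetic cohort generator

The generator emulates the structure of a two-arm survey of 792 male
prison inmates:

- **Categorical covariates** are drawn as exact-count permutations of the
  published sample marginals (education 125/377/207/83, nationality
  747/45, conduct 449/301/42; the published marital-status and crime
  columns sum to 790, so the two unaccounted records are assigned to the
  modal categories, single and "other crime"). Probability marginals are
  also accepted, and `default_config(n=...)` rescales counts automatically
  for other cohort sizes. Covariates are drawn independently of one
  another — the real survey's cross-covariate dependence is not modelled.
- **Continuous covariates** are distributional stand-ins with the
  published moments (only means/sds are available): age ~ normal(37.01,
  9.317) truncated to the inclusion range [18, 55]; sentence length ~
  log-normal matched to mean 69.76 / sd 72.626 months; severity score ~
  normal(7.34, 7.121) truncated to [0, 40], rounded to integers.
- **Latent statuses** come from a per-behaviour logistic model whose
  covariate coefficients default to the published regression point
  estimates (theft, drugs, arson; zero for violence and speeding, for
  which no stable model was reported) and whose intercept is calibrated
  per cohort by root finding so the cohort-mean latent probability equals
  the target prevalence exactly (0.8329, 0.9983, 0.5867, 0.9418, 0.2679 —
  the published indirect estimates). Statuses are independent across
  behaviours given covariates; cross-behaviour correlation is not
  modelled.
- **Arms**: a seeded uniform permutation assigns `round(n·arm_split)`
  respondents to the indirect arm (396/396 at the defaults; the real
  survey never reported its arm sizes, so the even split is an
  assumption).
- **Responses**: the indirect arm passes latent statuses through the
  device; the direct arm under-reports one-sidedly with per-behaviour
  report rates defaulting to the ratio of the published direct to indirect
  estimates (theft 0.692, drugs 0.703, violence 0.512, speeding 0.766,
  arson 0.280).

One master seed spawns independent substreams for generation, assignment
and response, so pipeline runs are byte-identical given the seed and
adding a stage does not perturb earlier stages' draws.

What passing tests on these cohorts do **not** show: robustness to
respondent cheating under the device, to false confessions, to covariate
dependence, to cluster structure within the prison, or to any sampling
design other than simple random sampling.

## Severity scale

Only the ten-item total severity score (0–40) of the obsessive-compulsive
scale is implemented, with the published bands low (8–15), moderate
(16–23), severe (24–31), very severe (32–40); totals 0–7 receive the
package-defined label "subthreshold". The symptom checklist and the
separate obsession/compulsion subscales are out of scope. When per-item
columns are present in a respondent file the total is recomputed and
mismatches are logged (the recomputed total wins).

## Problem sizes used in the checks

Monte Carlo checks use 5,000 replications for coverage and type-I error,
2,000 for estimator bias, 500 for stepwise behaviour, 400 for power, and
200 for end-to-end recovery and coefficient recovery — sizes at which the
Monte Carlo error is small against the asserted tolerances while the full
suite stays quick.

## Known limitations

- The variance estimator assumes simple random sampling within arms; the
  printed variances of the motivating survey are not exactly reproducible
  without its microdata and sampling-design details.
- The Pearson GOF p-value is conservative for ungrouped binary data (see
  above).
- Effect sizes are Cohen's h; no attempt is made to reproduce effect-size
  conventions that cannot be derived from two proportions alone.
- The regression supports any of the five behaviours as outcome, but only
  fixed-effects models; no random effects, penalization, or Bayesian
  variants.
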