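"""Logistic regression for randomized binary responses.

Each respondent's observed answer is a misclassified version of the
latent trait: the device (or direct questioning) maps the latent success
probability ``mu_i = expit(x_i' beta)`` to the observed "yes"
probability

    p*_i = c_i + d_i * mu_i,

with a per-respondent misclassification pair ``(c_i, d_i)`` — ``(0, 1)``
for direct questioning, ``(c, d)`` of the device for the indirect arm.
The model is fitted by maximum likelihood over the joint sample (both
arms in a single fit, each row carrying its own device line, with the
questioning method also available as a covariate for residual reporting
differences).  With all ``(c_i, d_i) = (0, 1)`` the likelihood reduces
exactly to textbook logistic regression, which serves as the strongest
correctness anchor.

Inference is Wald (standard errors from the inverse observed information
at the optimum), model selection is bidirectional stepwise on AIC with
categorical terms moving as whole blocks, and goodness of fit is the
Pearson statistic on the observed-response scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
from sklearn.base import BaseEstimator

from .cohort import CATEGORICAL_LEVELS
from .design import RRDesign, STUDY_DESIGN

__all__ = [
    "rr_loglik",
    "RRLogisticRegression",
    "RRGLMFit",
    "build_design_matrix",
    "fit_rr_model",
    "stepwise_select",
    "pearson_statistic",
    "pearson_gof",
    "odds_ratio_table",
]

logger = logging.getLogger(__name__)

_MU_CLIP = 1e-12

#: Covariate terms usable in model formulas: categorical terms expand to
#: dummy blocks against their reference (first) level, numeric terms enter
#: as single columns.  "method" is the questioning-arm indicator.
CATEGORICAL_TERMS = {"method": ("direct", "indirect"), **CATEGORICAL_LEVELS}
NUMERIC_TERMS = ("age", "sentence_months", "oc_score")


def _prepare_cd(c, d, n):
    c = np.broadcast_to(np.asarray(c, dtype=float), (n,)).copy()
    d = np.broadcast_to(np.asarray(d, dtype=float), (n,)).copy()
    if np.any(c < 0) or np.any(c + d > 1 + 1e-12) or np.any(d <= 0):
        raise ValueError(
            "misclassification pairs must satisfy 0 <= c, c + d <= 1, d > 0"
        )
    return c, d


def _mu(eta):
    return np.clip(expit(eta), _MU_CLIP, 1.0 - _MU_CLIP)


def rr_loglik(beta, X, y, c, d):
    """Log-likelihood and analytic gradient of the misclassified logit model.

    ``ell(beta) = sum_i y_i log(p*_i) + (1 - y_i) log(1 - p*_i)`` with
    ``p*_i = c_i + d_i * expit(x_i' beta)``.  The latent probability is
    clipped away from 0/1 at 1e-12 so rows with ``c_i = 0`` or
    ``c_i + d_i = 1`` stay finite for every finite beta.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    c, d = _prepare_cd(c, d, X.shape[0])
    mu = _mu(X @ beta)
    lam = c + d * mu
    ll = float(np.sum(y * np.log(lam) + (1.0 - y) * np.log1p(-lam)))
    resid = (y - lam) / (lam * (1.0 - lam))
    grad = X.T @ (resid * d * mu * (1.0 - mu))
    return ll, grad


def _rr_hessian(beta, X, y, c, d):
    """Observed-information Hessian of the log-likelihood (k x k)."""
    mu = _mu(X @ beta)
    lam = c + d * mu
    dmu = d * mu * (1.0 - mu)
    a = y / lam - (1.0 - y) / (1.0 - lam)
    a_prime = -(y / lam**2 + (1.0 - y) / (1.0 - lam) ** 2)
    h = a_prime * dmu**2 + a * dmu * (1.0 - 2.0 * mu)
    return (X * h[:, None]).T @ X


class RRLogisticRegression(BaseEstimator):
    """Maximum-likelihood logistic regression under response misclassification.

    scikit-learn-style estimator.  ``X`` is the covariate matrix without
    an intercept column (one is prepended when ``fit_intercept`` is
    true); the per-row misclassification pair may be given as scalars at
    construction or per-row arrays at fit time.

    Parameters
    ----------
    c, d : float, default (0, 1)
        Misclassification intercept and slope applied to every row unless
        overridden in :meth:`fit`; the default is direct questioning,
        under which this is ordinary logistic regression.
    fit_intercept : bool, default True
    max_iter : int, default 100
    tol : float, default 1e-8
        Convergence threshold on the gradient max-norm.

    Attributes
    ----------
    params_ : (k,) full coefficient vector (intercept first when fitted)
    intercept_ : float
    coef_ : (p,) covariate coefficients
    bse_ : (k,) Wald standard errors from the inverse observed information
    wald_z_, pvalues_ : per-coefficient two-sided normal tests
    odds_ratios_ : exp(params_)
    loglik_, aic_ : fit quality; ``aic_ = 2k - 2 loglik_``
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, c=0.0, d=1.0, fit_intercept=True, max_iter=100, tol=1e-8):
        self.c = c
        self.d = d
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.tol = tol

    @classmethod
    def from_design(cls, design: RRDesign, **kwargs) -> "RRLogisticRegression":
        return cls(c=design.c, d=design.d, **kwargs)

    # -- fitting ---------------------------------------------------------

    def _design(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        return X

    def fit(self, X, y, c=None, d=None, column_names=None):
        Xd = self._design(X)
        y = np.asarray(y, dtype=float).ravel()
        n, k = Xd.shape
        if n <= k:
            raise ValueError(f"need more rows ({n}) than parameters ({k})")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("responses must be binary (0/1)")
        rank = np.linalg.matrix_rank(Xd)
        if rank < k:
            names = list(column_names) if column_names else [f"x{j}" for j in range(k)]
            if self.fit_intercept and len(names) == k - 1:
                names = ["(Intercept)"] + names
            culprits = _collinear_columns(Xd, names)
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < {k}); "
                f"collinear columns: {culprits}"
            )
        c, d = _prepare_cd(self.c if c is None else c, self.d if d is None else d, n)

        beta, ll, n_iter, converged = self._maximize(Xd, y, c, d)

        H = _rr_hessian(beta, Xd, y, c, d)
        info = -H
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:  # pragma: no cover - singular info
            cov = np.full((k, k), np.nan)
            se = np.full(k, np.nan)

        self.params_ = beta
        self.cov_params_ = cov
        self.bse_ = se
        with np.errstate(divide="ignore", invalid="ignore"):
            self.wald_z_ = beta / se
        self.pvalues_ = 2.0 * stats.norm.sf(np.abs(self.wald_z_))
        self.odds_ratios_ = np.exp(beta)
        self.loglik_ = ll
        self.aic_ = 2.0 * k - 2.0 * ll
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_ = n
        self.k_ = k
        self.c_ = c
        self.d_ = d
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        if not converged:
            logger.warning(
                "RR logistic fit did not converge in %d iterations "
                "(gradient max-norm %.3g)", n_iter,
                np.max(np.abs(rr_loglik(beta, Xd, y, c, d)[1])),
            )
        return self

    def _maximize(self, X, y, c, d):
        """Newton with backtracking line search from beta = 0; quasi-Newton
        fallback when the Hessian is not usable."""
        k = X.shape[1]
        beta = np.zeros(k)
        ll, grad = rr_loglik(beta, X, y, c, d)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            if np.max(np.abs(grad)) < self.tol:
                converged = True
                break
            H = _rr_hessian(beta, X, y, c, d)
            try:
                step = np.linalg.solve(-H, grad)
            except np.linalg.LinAlgError:
                step = None
            if step is None or step @ grad <= 0:
                beta, ll = self._bfgs(beta, X, y, c, d)
                _, grad = rr_loglik(beta, X, y, c, d)
                continue
            # backtracking Armijo search; the absolute slack keeps full
            # Newton steps acceptable at float precision near the optimum
            t = 1.0
            slack = 1e-10 * (1.0 + abs(ll))
            for _ in range(50):
                ll_new, grad_new = rr_loglik(beta + t * step, X, y, c, d)
                if ll_new >= ll + 1e-4 * t * (grad @ step) - slack:
                    break
                t /= 2.0
            else:  # pragma: no cover - line search exhausted
                beta, ll = self._bfgs(beta, X, y, c, d)
                _, grad = rr_loglik(beta, X, y, c, d)
                continue
            beta = beta + t * step
            ll, grad = ll_new, grad_new
        else:
            converged = np.max(np.abs(grad)) < self.tol
            it = self.max_iter
        return beta, ll, it, converged

    @staticmethod
    def _bfgs(beta, X, y, c, d):
        res = optimize.minimize(
            lambda b: -rr_loglik(b, X, y, c, d)[0],
            beta,
            jac=lambda b: -rr_loglik(b, X, y, c, d)[1],
            method="BFGS",
            options={"gtol": 1e-10, "maxiter": 500},
        )
        return res.x, -res.fun

    # -- prediction ------------------------------------------------------

    def predict_latent_proba(self, X):
        """Latent trait probability ``mu_i = expit(x_i' beta)``."""
        return expit(self._design(X) @ self.params_)

    def predict_response_proba(self, X, c=None, d=None):
        """Observed-answer probability ``p*_i = c_i + d_i * mu_i``."""
        mu = self.predict_latent_proba(X)
        c, d = _prepare_cd(self.c if c is None else c, self.d if d is None else d, mu.size)
        return c + d * mu

    def predict(self, X):
        return (self.predict_latent_proba(X) >= 0.5).astype(int)


def _collinear_columns(X, names):
    """Name columns implicated in a rank deficiency (small QR diagonal)."""
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[j] for j in range(len(diag)) if diag[j] < tol]
    return bad or ["<undetermined>"]


# ---------------------------------------------------------------------------
# named-term interface over respondent DataFrames
# ---------------------------------------------------------------------------


def build_design_matrix(data: pd.DataFrame, terms):
    """Expand named terms into a covariate matrix (no intercept column).

    Categorical terms become dummy blocks against their reference level
    (first level of the vocabulary); numeric terms enter unchanged.
    Returns ``(X, names, blocks)`` where ``blocks`` maps each term to its
    column indices — stepwise selection moves whole blocks.
    """
    cols, names, blocks = [], [], {}
    for term in terms:
        start = len(names)
        if term in CATEGORICAL_TERMS:
            levels = CATEGORICAL_TERMS[term]
            values = data[term if term != "method" else "arm"].to_numpy()
            unknown = set(values) - set(levels)
            if unknown:
                raise ValueError(f"unknown {term!r} labels: {sorted(unknown)}")
            for level in levels[1:]:
                cols.append((values == level).astype(float))
                names.append(f"{term}[{level}]")
        elif term in NUMERIC_TERMS or term in data.columns:
            cols.append(data[term].to_numpy(dtype=float))
            names.append(term)
        else:
            raise ValueError(f"unknown model term {term!r}")
        blocks[term] = list(range(start, len(names)))
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return X, names, blocks


@dataclass
class RRGLMFit:
    """Fitted misclassified-response logistic model with named terms."""

    outcome: str
    terms: list
    names: list  # coefficient names, intercept first
    beta: np.ndarray
    se: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    odds_ratio: np.ndarray
    loglik: float
    aic: float
    pearson_x2: float
    pearson_p: float
    n: int
    k: int
    converged: bool
    iterations: int
    model: RRLogisticRegression = field(repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.beta,
                "std_error": self.se,
                "exp_estimate": self.odds_ratio,
                "p_value": self.wald_p,
            }
        )


def _row_cd(data: pd.DataFrame, design: RRDesign):
    indirect = (data["arm"] == "indirect").to_numpy()
    c = np.where(indirect, design.c, 0.0)
    d = np.where(indirect, design.d, 1.0)
    return c, d


def fit_rr_model(
    data: pd.DataFrame,
    outcome: str,
    terms,
    design: RRDesign = STUDY_DESIGN,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> RRGLMFit:
    """Fit the misclassified-response logistic model for one behaviour.

    ``outcome`` is a behaviour name (column ``resp_<outcome>``) or a
    response column name.  Rows carry ``(0, 1)`` in the direct arm and
    the device's ``(c, d)`` in the indirect arm; ``terms`` are named
    covariates (see :func:`build_design_matrix`).
    """
    col = outcome if outcome in data.columns else f"resp_{outcome}"
    if col not in data.columns:
        raise ValueError(f"outcome {outcome!r} absent from data")
    y = data[col].to_numpy(dtype=float)
    X, names, blocks = build_design_matrix(data, terms)
    c, d = _row_cd(data, design)
    est = RRLogisticRegression(fit_intercept=True, max_iter=max_iter, tol=tol)
    est.fit(X, y, c=c, d=d, column_names=names)
    x2, p = pearson_gof(est, X, y, c=c, d=d)
    return RRGLMFit(
        outcome=outcome,
        terms=list(terms),
        names=["(Intercept)"] + names,
        beta=est.params_,
        se=est.bse_,
        wald_z=est.wald_z_,
        wald_p=est.pvalues_,
        odds_ratio=est.odds_ratios_,
        loglik=est.loglik_,
        aic=est.aic_,
        pearson_x2=x2,
        pearson_p=p,
        n=est.n_,
        k=est.k_,
        converged=est.converged_,
        iterations=est.n_iter_,
        model=est,
    )


def aic(fit: RRGLMFit) -> float:
    """Akaike Information Criterion, ``2k - 2 log-likelihood``."""
    return fit.aic


def stepwise_select(
    data: pd.DataFrame,
    outcome: str,
    candidate_terms,
    design: RRDesign = STUDY_DESIGN,
    keep=("method",),
    max_steps: int = 50,
) -> RRGLMFit:
    """Bidirectional stepwise AIC selection over named terms.

    Starts from the full model; at each step evaluates every single-term
    removal and every single-term addition (whole dummy blocks move
    together), takes the move with the lowest AIC, and stops at a local
    minimum.  Terms in ``keep`` (by default the questioning method, the
    design variable of interest) are never dropped.
    """
    candidate_terms = list(candidate_terms)
    for term in keep:
        if term not in candidate_terms:
            raise ValueError(f"kept term {term!r} missing from candidates")
    current = list(candidate_terms)
    best = fit_rr_model(data, outcome, current, design)
    for _ in range(max_steps):
        moves = []
        for term in current:
            if term in keep:
                continue
            moves.append([t for t in current if t != term])
        for term in candidate_terms:
            if term not in current:
                moves.append(current + [term])
        improved = False
        for terms in moves:
            trial = fit_rr_model(data, outcome, terms, design)
            if trial.aic < best.aic - 1e-10:
                best, current, improved = trial, terms, True
        if not improved:
            break
    return best


def pearson_statistic(y, p_star, clip: float = 1e-12) -> float:
    """Pearson chi-square statistic on the observed-response scale.

    ``X^2 = sum_i (y_i - p*_i)^2 / (p*_i (1 - p*_i))``; fitted response
    probabilities within ``clip`` of 0 or 1 are clipped (and the event
    logged) so boundary rows contribute finitely.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p_star, dtype=float)
    n_clipped = int(np.sum((p < clip) | (p > 1.0 - clip)))
    if n_clipped:
        logger.info("pearson_statistic: clipped %d boundary fitted probabilities", n_clipped)
        p = np.clip(p, clip, 1.0 - clip)
    return float(np.sum((y - p) ** 2 / (p * (1.0 - p))))


def pearson_gof(model: RRLogisticRegression, X, y, c=None, d=None):
    """Pearson goodness-of-fit statistic and chi-square p-value.

    Degrees of freedom are ``n - k`` (residual).  Note that for
    ungrouped binary data the chi-square reference is approximate.
    """
    if not getattr(model, "converged_", False):
        logger.warning("Pearson GOF computed on a non-converged fit")
    p_star = model.predict_response_proba(
        X, c=model.c_ if c is None else c, d=model.d_ if d is None else d
    )
    x2 = pearson_statistic(np.asarray(y, dtype=float), p_star)
    df = model.n_ - model.k_
    return x2, float(stats.chi2.sf(x2, df))


def odds_ratio_table(fit: RRGLMFit, decimals: int = 4) -> pd.DataFrame:
    """Report rows: estimate, std. error, exp(estimate), p-value.

    Numbers are formatted to ``decimals`` decimal places as strings, the
    convention of the published regression tables; reference classes are
    implicit (absorbed in the intercept) and each dummy row is labelled
    ``term[level]``.
    """
    fmt = f"{{:.{decimals}f}}"
    return pd.DataFrame(
        {
            "term": fit.names,
            "estimate": [fmt.format(v) for v in fit.beta],
            "std_error": [fmt.format(v) for v in fit.se],
            "exp_estimate": [fmt.format(v) for v in fit.odds_ratio],
            "p_value": [fmt.format(v) for v in fit.wald_p],
        }
    )
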