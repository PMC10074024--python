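"""Regression engine: GLM fits, information criteria, out-of-sample R².

Linear models are fit by least squares (minimum-norm when the design is
rank deficient, which happens by construction: complementary templates
such as '0X' and '1X' sum to the intercept).  Logistic models are fit by
iteratively reweighted least squares (IRLS).  Both return an in-sample
log-likelihood used by AIC/BIC and the forward-selection engine.

Out-of-sample performance is the covariate-adjusted variance explained:

* linear:    R² = 1 − RSS_full / RSS_cov
* logistic:  R² = 1 − ℓ_full / ℓ_cov   (McFadden-style likelihood ratio)

where the "cov" reference is an intercept-plus-covariates model trained
on the same training data, and everything is evaluated on the held-out
fold.  Negative values signal overfitting and are returned as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "PhenotypeTable",
    "FittedModel",
    "fit_glm",
    "null_fit",
    "predict",
    "out_of_sample_r2",
    "information_criterion",
]

#: convergence tolerance on the relative log-likelihood change in IRLS
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
#: probability clip for test-fold logistic log-likelihoods
PROB_CLIP = 1e-12
#: residual-sum-of-squares floor (perfect fits would give infinite ML loglik)
RSS_FLOOR = 1e-10


@dataclass
class PhenotypeTable:
    """One outcome plus optional fixed covariates for ``n`` samples.

    ``family`` is ``"linear"`` for a continuous outcome or ``"logistic"``
    for a binary 0/1 outcome.  Covariates are always included in every
    model and never penalized.
    """

    y: np.ndarray
    covariates: np.ndarray | None = None
    family: str = "linear"
    sample_ids: list | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.size
        if self.covariates is None:
            self.covariates = np.empty((n, 0))
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        if self.covariates.shape[0] != n:
            raise ValueError("covariates and y disagree on sample count")
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "logistic":
            vals = np.unique(self.y)
            if not np.all(np.isin(vals, [0.0, 1.0])):
                raise ValueError("logistic family requires a 0/1 outcome")
        if np.isnan(self.y).any() or np.isnan(self.covariates).any():
            raise ValueError("missing values in phenotype or covariates")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def subset(self, idx: np.ndarray) -> "PhenotypeTable":
        ids = None
        if self.sample_ids is not None:
            ids = [self.sample_ids[i] for i in np.atleast_1d(idx)]
        return PhenotypeTable(self.y[idx], self.covariates[idx], self.family, ids)


@dataclass
class FittedModel:
    """A fitted GLM: intercept + covariates + template features.

    ``coef`` is laid out as [intercept, covariates..., features...].
    ``degenerate`` flags rank deficiency, non-convergence or separation;
    such models still yield predictions and must lose in validation
    rather than crash a CV sweep.
    """

    feature_names: tuple[str, ...]
    coef: np.ndarray
    loglik: float
    family: str
    n_covariates: int
    n_obs: int
    degenerate: bool = False

    @property
    def n_params(self) -> int:
        """Parameter count for information criteria.

        Counts all mean parameters plus, for the linear family, the
        error variance (the R ``glm``/``AIC`` convention).
        """
        return self.coef.size + (1 if self.family == "linear" else 0)


def _design(X: np.ndarray | None, cov: np.ndarray, n: int) -> np.ndarray:
    parts = [np.ones((n, 1)), cov]
    if X is not None and X.size:
        parts.append(np.asarray(X, dtype=float))
    return np.concatenate(parts, axis=1)


def _gaussian_loglik(rss: float, n: int) -> float:
    rss = max(rss, RSS_FLOOR)
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(y @ np.log(p) + (1.0 - y) @ np.log1p(-p))


def _fit_linear(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(np.sum((y - A @ beta) ** 2))
    return beta, rss, rank < A.shape[1]


def _fit_logistic(
    A: np.ndarray, y: np.ndarray, start: np.ndarray | None = None
) -> tuple[np.ndarray, float, bool]:
    """IRLS fit; returns (coef, loglik, degenerate)."""
    n, m = A.shape
    beta = np.zeros(m) if start is None else np.asarray(start, dtype=float).copy()
    eta = A @ beta
    p = expit(eta)
    ll = _bernoulli_loglik(y, p)
    degenerate = False
    for _ in range(IRLS_MAX_ITER):
        w = np.clip(p * (1.0 - p), 1e-10, None)
        z = eta + (y - p) / w
        aw = A * w[:, None]
        gram = A.T @ aw
        rhs = aw.T @ z
        try:
            beta_new = np.linalg.solve(gram, rhs)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(gram, rhs, rcond=None)[0]
            degenerate = True
        eta_new = A @ beta_new
        p_new = expit(eta_new)
        ll_new = _bernoulli_loglik(y, p_new)
        # step-halving keeps IRLS monotone near separation
        step = 1.0
        while ll_new < ll - 1e-10 and step > 1e-4:
            step /= 2.0
            beta_new = beta + step * (beta_new - beta)
            eta_new = A @ beta_new
            p_new = expit(eta_new)
            ll_new = _bernoulli_loglik(y, p_new)
        converged = abs(ll_new - ll) <= IRLS_TOL * (abs(ll) + 1.0)
        beta, eta, p, ll = beta_new, eta_new, p_new, ll_new
        if converged:
            break
    else:
        degenerate = True
    if np.abs(beta).max(initial=0.0) > 50.0:
        degenerate = True  # effectively separated
    return beta, ll, degenerate


def fit_glm(
    X: np.ndarray | None,
    pheno: PhenotypeTable,
    feature_names: Sequence[str] = (),
    start: np.ndarray | None = None,
) -> FittedModel:
    """Maximum-likelihood fit of phenotype on features plus covariates.

    ``X`` holds the template-dosage columns (may be ``None``/empty for
    the covariate-only null model); covariates from ``pheno`` are always
    included.  ``start`` optionally warm-starts logistic IRLS.
    """
    n = pheno.n
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n:
            raise ValueError("feature matrix and phenotype disagree on n")
    A = _design(X, pheno.covariates, n)
    names = tuple(feature_names)
    if X is not None and X.size and len(names) != X.shape[1]:
        names = tuple(f"x{j}" for j in range(X.shape[1]))
    if pheno.family == "linear":
        beta, rss, degen = _fit_linear(A, pheno.y)
        ll = _gaussian_loglik(rss, n)
    else:
        if len(np.unique(pheno.y)) < 2:
            raise ValueError("logistic fit requires both outcome classes")
        beta, ll, degen = _fit_logistic(A, pheno.y, start=start)
    return FittedModel(
        feature_names=names,
        coef=beta,
        loglik=float(ll),
        family=pheno.family,
        n_covariates=pheno.n_covariates,
        n_obs=n,
        degenerate=degen,
    )


def null_fit(pheno: PhenotypeTable) -> FittedModel:
    """Covariate-plus-intercept-only reference model."""
    return fit_glm(None, pheno)


def predict(
    model: FittedModel, X: np.ndarray | None, covariates: np.ndarray
) -> np.ndarray:
    """Model predictions: conditional mean (linear) or probability."""
    n = covariates.shape[0] if covariates.ndim == 2 else len(covariates)
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = X.shape[0]
    A = _design(X, np.asarray(covariates, dtype=float).reshape(n, -1), n)
    eta = A @ model.coef
    return expit(eta) if model.family == "logistic" else eta


def out_of_sample_r2(
    model: FittedModel,
    null_model: FittedModel,
    X_test: np.ndarray | None,
    pheno_test: PhenotypeTable,
) -> float:
    """Covariate-adjusted variance explained on a held-out fold.

    Both ``model`` and ``null_model`` must have been trained on the same
    (disjoint) training data.  May be negative when the full model
    generalizes worse than the covariate-only reference — negative values
    are returned unclamped because they diagnose overfitting.
    """
    if pheno_test.n == 0:
        raise ValueError("empty test fold")
    y = pheno_test.y
    cov = pheno_test.covariates
    pred_full = predict(model, X_test, cov)
    pred_null = predict(null_model, None, cov)
    if model.family == "linear":
        rss_full = float(np.sum((y - pred_full) ** 2))
        rss_null = float(np.sum((y - pred_null) ** 2))
        if rss_null <= RSS_FLOOR:
            return 0.0
        return 1.0 - rss_full / rss_null
    ll_full = _bernoulli_loglik(y, pred_full)
    ll_null = _bernoulli_loglik(y, pred_null)
    if ll_null > -RSS_FLOOR:  # null predicts the fold perfectly
        return 0.0
    return 1.0 - ll_full / ll_null


def information_criterion(model: FittedModel, kind: str) -> float:
    """AIC = 2m − 2ℓ or BIC = m·ln(n) − 2ℓ for a fitted model."""
    m, ll, n = model.n_params, model.loglik, model.n_obs
    k = kind.lower()
    if k == "aic":
        return 2.0 * m - 2.0 * ll
    if k == "bic":
        return m * np.log(n) - 2.0 * ll
    raise ValueError(f"unknown information criterion {kind!r}")
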