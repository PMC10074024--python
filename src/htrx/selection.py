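"""Candidate-model generation: forward selection and lasso paths.

Three penalties produce candidate template sets:

* **AIC / BIC** — greedy forward regression; at each step the feature
  giving the best criterion improvement enters, and the path stops when
  no addition improves the criterion.
* **loglik** — unpenalized forward regression used by cumulative growth:
  exactly ``max_steps`` greedy steps ranked by in-sample log-likelihood.
* **lasso** — an L1 regularization path; the distinct non-zero supports
  along the path are refit without penalty and scored by BIC.

Covariates and the intercept are always unpenalized.  Tie-breaks go to
the lowest canonical template order (features are presented in canonical
order, so the first best index wins), which makes paths deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.linear_model import lasso_path as _sk_lasso_path

from .model_fit import (
    FittedModel,
    PhenotypeTable,
    _bernoulli_loglik,
    _design,
    _gaussian_loglik,
    fit_glm,
    information_criterion,
    null_fit,
)
from .templates import canonical_sort

__all__ = [
    "CandidateModel",
    "ForwardPath",
    "forward_path",
    "candidates_from_penalty",
    "retain_best_M",
]

#: above this many remaining features, logistic forward steps pre-screen
#: candidates by Rao score statistic and exact-refit only the top ones
LOGISTIC_SCREEN = 40

#: lasso path grid: n_lambdas log-spaced down to eps * lambda_max
LASSO_N_LAMBDAS = 100
LASSO_EPS = 1e-4


@dataclass(frozen=True)
class CandidateModel:
    """A template set competing in stage-2 CV.

    Identity is the template set alone: two replicates proposing the same
    set are the same candidate (deduplication key :meth:`key`).
    """

    templates: tuple[str, ...]
    penalty: str = ""
    criterion: float = np.nan
    source: int = -1

    def key(self) -> tuple[str, ...]:
        return tuple(canonical_sort(self.templates))

    @property
    def size(self) -> int:
        return len(self.templates)


@dataclass
class ForwardPath:
    """A greedy nested path of models.

    ``selected`` lists feature names in entry order; ``criteria`` holds
    the per-prefix criterion value starting with the empty model, so
    ``criteria[s]`` scores the prefix of length ``s``.
    """

    selected: list[str]
    criteria: list[float]
    criterion: str
    logliks: list[float] = field(default_factory=list)

    def prefix(self, s: int) -> tuple[str, ...]:
        return tuple(self.selected[:s])

    def __len__(self) -> int:
        return len(self.selected)


def _ic_value(ll: float, m: int, n: int, criterion: str) -> float:
    if criterion == "aic":
        return 2.0 * m - 2.0 * ll
    if criterion == "bic":
        return m * np.log(n) - 2.0 * ll
    return -ll  # loglik path: lower is better for a uniform "criterion"


def _forward_linear(
    F: np.ndarray,
    names: Sequence[str],
    pheno: PhenotypeTable,
    criterion: str,
    max_steps: int | None,
) -> ForwardPath:
    n, p = F.shape
    y = pheno.y
    A0 = _design(None, pheno.covariates, n)
    m0 = A0.shape[1] + 1  # + error variance
    q0, _ = np.linalg.qr(A0)
    r = y - q0 @ (q0.T @ y)
    Fr = F - q0 @ (q0.T @ F)
    norms = np.einsum("ij,ij->j", Fr, Fr)
    floor = 1e-8 * (norms + 1.0)
    rss = float(r @ r)
    eligible = norms > floor
    limit = p if max_steps is None else min(max_steps, p)
    ll = _gaussian_loglik(rss, n)
    crit = _ic_value(ll, m0, n, criterion)
    path = ForwardPath([], [crit], criterion, [ll])
    while len(path) < limit if criterion == "loglik" else True:
        if not eligible.any() or (criterion != "loglik" and max_steps is not None and len(path) >= max_steps):
            break
        proj = Fr.T @ r
        gains = np.where(eligible, proj**2 / np.where(norms > 0, norms, 1.0), -np.inf)
        j = int(np.argmax(gains))
        gain = gains[j]
        if not np.isfinite(gain) or gain <= 0:
            break
        new_rss = max(rss - gain, 0.0)
        new_ll = _gaussian_loglik(new_rss, n)
        new_crit = _ic_value(new_ll, m0 + len(path) + 1, n, criterion)
        if criterion != "loglik" and new_crit >= path.criteria[-1]:
            break
        qv = Fr[:, j] / np.sqrt(norms[j])
        r = r - qv * (qv @ r)
        load = qv @ Fr
        Fr = Fr - np.outer(qv, load)
        norms = np.maximum(norms - load**2, 0.0)
        eligible &= norms > floor
        eligible[j] = False
        rss = float(r @ r)
        path.selected.append(names[j])
        path.criteria.append(new_crit)
        path.logliks.append(new_ll)
        if criterion == "loglik" and len(path) >= limit:
            break
    return path


def _score_screen(
    A_cur: np.ndarray, coef: np.ndarray, y: np.ndarray, F_rem: np.ndarray
) -> np.ndarray:
    """Rao score statistic of each remaining feature at the current fit."""
    eta = A_cur @ coef
    p = expit(eta)
    w = np.clip(p * (1.0 - p), 1e-10, None)
    u = F_rem.T @ (y - p)
    wf = F_rem * w[:, None]
    v1 = np.einsum("ij,ij->j", F_rem, wf)
    awf = A_cur.T @ wf
    gram = A_cur.T @ (A_cur * w[:, None])
    try:
        sol = np.linalg.solve(gram, awf)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(gram, awf, rcond=None)[0]
    v = np.clip(v1 - np.einsum("ij,ij->j", awf, sol), 1e-12, None)
    return u**2 / v


def _forward_logistic(
    F: np.ndarray,
    names: Sequence[str],
    pheno: PhenotypeTable,
    criterion: str,
    max_steps: int | None,
) -> ForwardPath:
    n, p = F.shape
    y = pheno.y
    m0 = pheno.n_covariates + 1
    current = fit_glm(None, pheno)
    sel_idx: list[int] = []
    crit = _ic_value(current.loglik, m0, n, criterion)
    path = ForwardPath([], [crit], criterion, [current.loglik])
    remaining = list(range(p))
    limit = p if max_steps is None else min(max_steps, p)
    while remaining:
        if criterion == "loglik" and len(path) >= limit:
            break
        if criterion != "loglik" and max_steps is not None and len(path) >= max_steps:
            break
        X_cur = F[:, sel_idx] if sel_idx else None
        if len(remaining) > LOGISTIC_SCREEN:
            A_cur = _design(X_cur, pheno.covariates, n)
            scores = _score_screen(A_cur, current.coef, y, F[:, remaining])
            top = np.argsort(scores)[::-1][:LOGISTIC_SCREEN]
            cand = sorted(remaining[i] for i in top)
        else:
            cand = list(remaining)
        best_j, best_fit = -1, None
        for j in cand:
            X_try = F[:, sel_idx + [j]]
            start = np.append(current.coef, 0.0)
            fit = fit_glm(X_try, pheno, start=start)
            if best_fit is None or fit.loglik > best_fit.loglik + 1e-12:
                best_j, best_fit = j, fit
        if best_fit is None or best_fit.loglik <= current.loglik + 1e-12:
            break
        new_crit = _ic_value(best_fit.loglik, m0 + len(path) + 1, n, criterion)
        if criterion != "loglik" and new_crit >= path.criteria[-1]:
            break
        sel_idx.append(best_j)
        remaining.remove(best_j)
        current = best_fit
        path.selected.append(names[best_j])
        path.criteria.append(new_crit)
        path.logliks.append(best_fit.loglik)
    return path


def forward_path(
    F: np.ndarray,
    names: Sequence[str],
    pheno: PhenotypeTable,
    criterion: str = "bic",
    max_steps: int | None = None,
) -> ForwardPath:
    """Greedy forward-selection path of template features.

    ``criterion`` is ``"aic"``, ``"bic"`` (penalized; stops when no
    addition improves the criterion) or ``"loglik"`` (unpenalized;
    requires ``max_steps`` and runs exactly that many steps or until
    informative features are exhausted).
    """
    criterion = criterion.lower()
    if criterion not in ("aic", "bic", "loglik"):
        raise ValueError(f"unknown forward criterion {criterion!r}")
    if criterion == "loglik" and max_steps is None:
        raise ValueError("max_steps is required for the unpenalized loglik path")
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[1] == 0:
        raise ValueError("at least one feature is required")
    if len(names) != F.shape[1]:
        raise ValueError("names must label every feature column")
    if pheno.family == "linear":
        path = _forward_linear(F, list(names), pheno, criterion, max_steps)
    else:
        path = _forward_logistic(F, list(names), pheno, criterion, max_steps)
    if criterion == "loglik" and len(path) < min(max_steps, F.shape[1]):
        # informative features exhausted (collinearity): fill remaining
        # slots in canonical order with zero-gain features so retention
        # keeps exactly min(M, p) and stays lossless for large M
        chosen = set(path.selected)
        for nm in names:
            if len(path) >= min(max_steps, F.shape[1]):
                break
            if nm not in chosen:
                path.selected.append(nm)
                path.criteria.append(path.criteria[-1])
                path.logliks.append(path.logliks[-1])
    return path


def retain_best_M(
    F: np.ndarray, names: Sequence[str], pheno: PhenotypeTable, M: int
) -> list[str]:
    """Best ``M`` features by unpenalized forward regression (in order)."""
    if M < 1:
        raise ValueError("M must be >= 1")
    path = forward_path(F, names, pheno, criterion="loglik", max_steps=M)
    return list(path.selected)


def _power_spectral_norm(A: np.ndarray, iters: int = 30) -> float:
    rng = np.random.default_rng(0)
    v = rng.standard_normal(A.shape[1])
    v /= np.linalg.norm(v)
    s = 1.0
    for _ in range(iters):
        w = A.T @ (A @ v)
        s = np.linalg.norm(w)
        if s == 0:
            return 1.0
        v = w / s
    return float(np.sqrt(s))


def _logistic_l1_supports(
    Fs: np.ndarray, pheno: PhenotypeTable, lambdas: np.ndarray
) -> list[tuple[int, ...]]:
    """Pathwise FISTA for L1 logistic regression with unpenalized
    intercept and covariates; returns the support at each lambda."""
    n, p = Fs.shape
    A = _design(Fs, pheno.covariates, n)
    m0 = 1 + pheno.n_covariates
    pen = np.zeros(A.shape[1], dtype=bool)
    pen[m0:] = True
    y = pheno.y
    lip = _power_spectral_norm(A) ** 2 / (4.0 * n)
    step = 1.0 / max(lip, 1e-12)
    theta = np.zeros(A.shape[1])
    theta[0] = np.log(max(y.mean(), 1e-6) / max(1.0 - y.mean(), 1e-6))
    supports = []
    for lam in lambdas:
        x = theta.copy()
        zv = x.copy()
        t = 1.0
        obj_prev = np.inf
        for _ in range(500):
            eta = A @ zv
            pr = expit(eta)
            grad = A.T @ (pr - y) / n
            x_new = zv - step * grad
            x_new[pen] = np.sign(x_new[pen]) * np.maximum(
                np.abs(x_new[pen]) - step * lam, 0.0
            )
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            zv = x_new + ((t - 1.0) / t_new) * (x_new - x)
            x, t = x_new, t_new
            obj = -_bernoulli_loglik(y, expit(A @ x)) / n + lam * np.abs(x[pen]).sum()
            if abs(obj_prev - obj) <= 1e-7 * (abs(obj) + 1.0):
                break
            obj_prev = obj
        theta = x
        supports.append(tuple(np.flatnonzero(np.abs(x[m0:]) > 1e-8)))
    return supports


def _lasso_supports(
    F: np.ndarray, pheno: PhenotypeTable
) -> list[tuple[int, ...]]:
    """Distinct supports along the L1 path (largest penalty first).

    Features are standardized internally; intercept and covariates are
    never penalized (exactly, via Frisch–Waugh residualization for the
    linear family, and via a penalty mask for the logistic family).
    """
    n, p = F.shape
    mu = F.mean(axis=0)
    sd = F.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Fs = (F - mu) / sd
    if pheno.family == "linear":
        A0 = _design(None, pheno.covariates, n)
        q0, _ = np.linalg.qr(A0)
        y_res = pheno.y - q0 @ (q0.T @ pheno.y)
        F_res = Fs - q0 @ (q0.T @ Fs)
        _, coefs, _ = _sk_lasso_path(
            F_res, y_res, eps=LASSO_EPS, alphas=LASSO_N_LAMBDAS
        )
        supports = [
            tuple(np.flatnonzero(np.abs(coefs[:, a]) > 1e-10))
            for a in range(coefs.shape[1])
        ]
    else:
        nullm = null_fit(pheno)
        p0 = expit(_design(None, pheno.covariates, n) @ nullm.coef)
        lam_max = np.abs(Fs.T @ (pheno.y - p0)).max() / n
        lam_max = max(lam_max, 1e-10)
        lambdas = np.geomspace(lam_max, LASSO_EPS * lam_max, LASSO_N_LAMBDAS)
        supports = _logistic_l1_supports(Fs, pheno, lambdas)
    out, seen = [], set()
    for s in supports:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def candidates_from_penalty(
    F: np.ndarray,
    names: Sequence[str],
    pheno: PhenotypeTable,
    penalty: str = "bic",
    q: int = 3,
    source: int = -1,
) -> list[CandidateModel]:
    """Best ``q`` candidate template sets under a penalty.

    AIC/BIC: the ``q`` prefixes of the forward path with the lowest
    criterion value (the empty model is a legitimate prefix — under the
    null the correct candidate is "nothing").  Lasso: the distinct
    supports along the L1 path, refit without penalty and ranked by BIC.
    Fewer than ``q`` are returned when the path yields fewer distinct
    sets.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    penalty = penalty.lower()
    names = list(names)
    F = np.asarray(F, dtype=float)
    if penalty in ("aic", "bic"):
        path = forward_path(F, names, pheno, criterion=penalty)
        scored = [
            (path.criteria[s], path.prefix(s)) for s in range(len(path) + 1)
        ]
    elif penalty == "lasso":
        name_idx = {nm: i for i, nm in enumerate(names)}
        scored = []
        for sup in _lasso_supports(F, pheno):
            feats = tuple(names[i] for i in sup)
            cols = F[:, list(sup)] if sup else None
            fit = fit_glm(cols, pheno, feature_names=feats)
            scored.append((information_criterion(fit, "bic"), feats))
    else:
        raise ValueError(f"unknown penalty {penalty!r}")
    best: dict[tuple[str, ...], float] = {}
    for crit, feats in scored:
        key = tuple(canonical_sort(feats))
        if key not in best or crit < best[key]:
            best[key] = crit
    ranked = sorted(best.items(), key=lambda kv: (kv[1], len(kv[0]), kv[0]))
    return [
        CandidateModel(templates=key, penalty=penalty, criterion=crit, source=source)
        for key, crit in ranked[:q]
    ]
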