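"""Cross-validation engines: Direct-Fit, Direct CV and Two-stage CV.

Direct-Fit regresses the phenotype on every template at once — the
overfitting baseline.  Direct CV trains a penalized model inside each of
``k`` folds and averages held-out R², but the selected feature set may
differ per fold (an ensemble).  Two-stage CV separates the two concerns:

* **Stage 1** — ``B`` replicates each subsample a fraction ``D`` of the
  data and propose their best ``q`` candidate template sets under the
  configured penalty; the union is deduplicated to ``z`` candidates.
* **Stage 2** — the data are split into ``k`` folds; in iteration ``i``
  every candidate is refit *without* penalization on ``k − 2`` folds,
  validated on one fold and tested on the remaining one.  The winner
  maximizes mean validation R²; the headline score is the mean of the
  winner's *test* values, which never informed its selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dosage import HaplotypePanel, build_dosage_matrix
from .model_fit import (
    FittedModel,
    PhenotypeTable,
    fit_glm,
    null_fit,
    out_of_sample_r2,
)
from .selection import CandidateModel, candidates_from_penalty
from .templates import FeatureSetSpec, enumerate_templates

__all__ = [
    "HtrxConfig",
    "HtrxResult",
    "make_folds",
    "direct_fit",
    "direct_cv",
    "two_stage_cv",
]

logger = logging.getLogger(__name__)

_PENALTIES = ("aic", "bic", "lasso")


@dataclass
class HtrxConfig:
    """Tuning parameters for all HTRX algorithms.

    Defaults follow common practice for the method: ``k=10`` folds,
    ``B=10`` stage-1 replicates each on a fraction ``D=0.5`` of the
    data, ``q=3`` candidates per replicate, BIC penalization, and for
    cumulative growth ``L=6`` initial SNPs with ``M=50`` retained
    features.
    """

    k: int = 10
    B: int = 10
    D: float = 0.5
    q: int = 3
    penalty: str = "bic"
    family: str | None = None
    max_order: int | None = None
    htr_only: bool = False
    L: int = 6
    M: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k-fold CV requires k >= 3")
        if not (0.0 < self.D <= 1.0):
            raise ValueError("subsample fraction D must be in (0, 1]")
        if self.B < 1 or self.q < 1 or self.M < 1 or self.L < 1:
            raise ValueError("B, q, M and L must all be >= 1")
        self.penalty = self.penalty.lower()
        if self.penalty not in _PENALTIES:
            raise ValueError(f"penalty must be one of {_PENALTIES}")

    def feature_spec(self) -> FeatureSetSpec:
        return FeatureSetSpec(max_order=self.max_order, htr_only=self.htr_only)


@dataclass
class HtrxResult:
    """Outcome of an HTRX run.

    ``winner`` is the selected template set (``None`` for Direct CV,
    whose per-fold sets form an ensemble in ``fold_sets``); ``mean_r2``
    is the arithmetic mean of ``fold_test_r2`` — the headline
    out-of-sample variance explained.
    """

    algorithm: str
    winner: tuple[str, ...] | None
    fold_test_r2: np.ndarray
    mean_r2: float
    z: int
    candidates: list[CandidateModel] = field(default_factory=list)
    candidate_val_r2: dict[tuple[str, ...], float] = field(default_factory=dict)
    fold_sets: list[tuple[str, ...]] | None = None
    null_model_selected: bool = False
    stage1_max_width: int | None = None


def make_folds(
    n: int,
    k: int,
    seed: int | np.random.Generator | None = None,
    stratify_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Assign ``n`` samples to ``k`` folds of near-equal size.

    Deterministic given the seed.  With ``stratify_labels`` (binary case
    status for logistic outcomes) each class is dealt round-robin so per-
    fold class counts differ from proportionality by at most one sample.
    """
    if k < 3:
        raise ValueError("k-fold CV requires k >= 3")
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=int)
    if stratify_labels is None:
        perm = rng.permutation(n)
        labels[perm] = np.arange(n) % k
        return labels
    stratify_labels = np.asarray(stratify_labels)
    counter = 0
    for cls in np.unique(stratify_labels):
        members = np.flatnonzero(stratify_labels == cls)
        members = rng.permutation(members)
        labels[members] = (counter + np.arange(members.size)) % k
        counter += members.size
    return labels


def _subsample(
    rng: np.random.Generator,
    n: int,
    frac: float,
    stratify_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of a fraction of the samples, without replacement,
    stratified by class when labels are given."""
    if stratify_labels is None:
        m = max(1, int(round(frac * n)))
        return np.sort(rng.choice(n, size=m, replace=False))
    parts = []
    for cls in np.unique(stratify_labels):
        members = np.flatnonzero(stratify_labels == cls)
        m = max(1, int(round(frac * members.size)))
        parts.append(rng.choice(members, size=m, replace=False))
    return np.sort(np.concatenate(parts))


def build_features(
    panel: HaplotypePanel, spec: FeatureSetSpec | None
) -> tuple[np.ndarray, list[str]]:
    """Dosage feature matrix for every template allowed by ``spec``."""
    templates = enumerate_templates(panel.u, spec)
    df = build_dosage_matrix(panel, templates)
    return df.to_numpy(), templates


def _resolve_family(pheno: PhenotypeTable, cfg: HtrxConfig) -> None:
    if cfg.family is not None and cfg.family != pheno.family:
        raise ValueError(
            f"config family {cfg.family!r} != phenotype family {pheno.family!r}"
        )


def _strat(pheno: PhenotypeTable) -> np.ndarray | None:
    return pheno.y.astype(int) if pheno.family == "logistic" else None


def _fit_candidate(
    F: np.ndarray,
    name_idx: dict[str, int],
    cand: tuple[str, ...],
    idx: np.ndarray,
    pheno: PhenotypeTable,
) -> FittedModel:
    cols = [name_idx[t] for t in cand]
    X = F[np.ix_(idx, cols)] if cols else None
    return fit_glm(X, pheno.subset(idx), feature_names=cand)


def _eval_candidate(
    model: FittedModel,
    nullm: FittedModel,
    F: np.ndarray,
    name_idx: dict[str, int],
    idx: np.ndarray,
    pheno: PhenotypeTable,
) -> float:
    cols = [name_idx[t] for t in model.feature_names]
    X = F[np.ix_(idx, cols)] if cols else None
    return out_of_sample_r2(model, nullm, X, pheno.subset(idx))


def stage2_evaluate(
    F: np.ndarray,
    names: Sequence[str],
    pheno: PhenotypeTable,
    candidates: list[CandidateModel],
    cfg: HtrxConfig,
    fold_seed: int | np.random.Generator | None,
    algorithm: str,
) -> HtrxResult:
    """Stage-2 winner selection and scoring shared by Two-stage CV and
    cumulative HTRX.

    For fold-iteration ``i``: test fold = ``i``, validation fold =
    ``(i+1) mod k``, training = the remaining ``k−2`` folds, so every
    fold serves each role exactly once across the ``k`` iterations.
    """
    name_idx = {nm: i for i, nm in enumerate(names)}
    sets = []
    seen = set()
    for c in candidates:
        key = c.key()
        if key not in seen:
            seen.add(key)
            sets.append(key)
    if not sets:
        sets = [()]
    z = len(sets)
    k = cfg.k
    folds = make_folds(pheno.n, k, fold_seed, _strat(pheno))
    val_r2 = np.full((k, z), np.nan)
    test_r2 = np.full((k, z), np.nan)
    for i in range(k):
        test_mask = folds == i
        val_mask = folds == (i + 1) % k
        train_idx = np.flatnonzero(~test_mask & ~val_mask)
        val_idx = np.flatnonzero(val_mask)
        test_idx = np.flatnonzero(test_mask)
        pheno_train = pheno.subset(train_idx)
        nullm = null_fit(pheno_train)
        for j, cand in enumerate(sets):
            try:
                model = _fit_candidate(F, name_idx, cand, train_idx, pheno)
            except (ValueError, np.linalg.LinAlgError):
                continue  # leave NaN: candidate unfit in this rotation
            val_r2[i, j] = _eval_candidate(model, nullm, F, name_idx, val_idx, pheno)
            test_r2[i, j] = _eval_candidate(model, nullm, F, name_idx, test_idx, pheno)
    with np.errstate(invalid="ignore"):
        mean_val = np.nanmean(val_r2, axis=0)
    mean_val = np.where(np.isnan(mean_val), -np.inf, mean_val)
    order = sorted(
        range(z), key=lambda j: (-mean_val[j], len(sets[j]), sets[j])
    )
    j_star = order[0]
    winner = sets[j_star]
    fold_scores = test_r2[:, j_star]
    mean_score = float(np.nanmean(fold_scores)) if np.isfinite(mean_val[j_star]) else 0.0
    logger.info(
        "%s: z=%d candidates, winner=%s, mean test R2=%.5f",
        algorithm,
        z,
        list(winner) or "<null model>",
        mean_score,
    )
    return HtrxResult(
        algorithm=algorithm,
        winner=winner,
        fold_test_r2=fold_scores,
        mean_r2=mean_score,
        z=z,
        candidates=list(candidates),
        candidate_val_r2={sets[j]: float(mean_val[j]) for j in range(z)},
        null_model_selected=len(winner) == 0,
    )


def direct_fit(
    panel: HaplotypePanel,
    spec: FeatureSetSpec | None,
    pheno: PhenotypeTable,
    cfg: HtrxConfig | None = None,
) -> tuple[FittedModel, float]:
    """All-feature multivariate regression on all data (no penalty).

    Returns the fitted model and its *in-sample* R² against the
    covariate-only reference.  Use :func:`model_fit.out_of_sample_r2`
    with fresh data for an honest assessment — the gap between the two
    is the overfitting this method exists to exhibit.
    """
    if cfg is not None:
        _resolve_family(pheno, cfg)
    F, names = build_features(panel, spec)
    model = fit_glm(F, pheno, feature_names=names)
    nullm = null_fit(pheno)
    r2 = out_of_sample_r2(model, nullm, F, pheno)
    return model, r2


def direct_cv(
    panel: HaplotypePanel,
    spec: FeatureSetSpec | None,
    pheno: PhenotypeTable,
    cfg: HtrxConfig,
) -> HtrxResult:
    """k-fold CV with penalized training inside each fold.

    Each fold trains the configured penalty on the other ``k − 1`` folds,
    takes the single best model, and scores it on the held-out fold.  The
    per-fold feature sets may differ (``fold_sets``) — this engine scores
    an ensemble, not one fixed template set.
    """
    _resolve_family(pheno, cfg)
    F, names = build_features(panel, spec)
    name_idx = {nm: i for i, nm in enumerate(names)}
    ss = np.random.SeedSequence(cfg.seed)
    fold_rng, = ss.spawn(1)
    folds = make_folds(pheno.n, cfg.k, np.random.default_rng(fold_rng), _strat(pheno))
    fold_scores = np.empty(cfg.k)
    fold_sets: list[tuple[str, ...]] = []
    for i in range(cfg.k):
        train_idx = np.flatnonzero(folds != i)
        test_idx = np.flatnonzero(folds == i)
        pheno_train = pheno.subset(train_idx)
        cands = candidates_from_penalty(
            F[train_idx], names, pheno_train, cfg.penalty, q=1, source=i
        )
        best = cands[0].key() if cands else ()
        model = _fit_candidate(F, name_idx, best, train_idx, pheno)
        nullm = null_fit(pheno_train)
        fold_scores[i] = _eval_candidate(model, nullm, F, name_idx, test_idx, pheno)
        fold_sets.append(best)
        logger.debug("direct_cv fold %d: set=%s R2=%.5f", i, best, fold_scores[i])
    return HtrxResult(
        algorithm="direct-cv",
        winner=None,
        fold_test_r2=fold_scores,
        mean_r2=float(fold_scores.mean()),
        z=len({s for s in fold_sets}),
        fold_sets=fold_sets,
        null_model_selected=all(len(s) == 0 for s in fold_sets),
    )


def two_stage_cv(
    panel: HaplotypePanel,
    spec: FeatureSetSpec | None,
    pheno: PhenotypeTable,
    cfg: HtrxConfig,
) -> HtrxResult:
    """Two-stage CV: penalized candidate generation on subsamples, then
    unpenalized k-fold validation/test scoring of the deduplicated
    candidates (see module docstring for the full contract)."""
    _resolve_family(pheno, cfg)
    F, names = build_features(panel, spec)
    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(cfg.B + 1)
    strat = _strat(pheno)
    candidates: list[CandidateModel] = []
    for b in range(cfg.B):
        rng = np.random.default_rng(streams[b])
        idx = _subsample(rng, pheno.n, cfg.D, strat)
        cands = candidates_from_penalty(
            F[idx], names, pheno.subset(idx), cfg.penalty, q=cfg.q, source=b
        )
        logger.info(
            "stage1 replicate %d: %s",
            b,
            [(list(c.templates), round(c.criterion, 3)) for c in cands],
        )
        candidates.extend(cands)
    return stage2_evaluate(
        F,
        names,
        pheno,
        candidates,
        cfg,
        np.random.default_rng(streams[-1]),
        algorithm="two-stage",
    )
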