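"""Cumulative HTRX: bounded-width template growth for long regions.

Exhaustive template enumeration is exponential in the region size ``u``
(3**u − 1 features), which limits two-stage CV to u ≤ 6.  Cumulative
HTRX grows good template sets one SNP at a time instead: each stage-1
replicate starts from an exhaustive enumeration of ``L`` randomly
sampled SNPs, retains the best ``M`` features by unpenalized forward
regression, and then repeatedly (i) adds one more unused SNP, which
turns ``M`` retained templates into ``3M + 2`` candidates (each pattern
extended with '0'/'1'/'X' plus the two fresh single-SNP templates), and
(ii) prunes back to ``M``.  The final SNP closes the set *without*
pruning before penalized candidate selection, and stage 2 is the same
validation/test fold rotation as two-stage CV.  The design-matrix width
therefore never exceeds ``max(initial enumeration, 3M + 2)``, and the
compute time grows linearly in ``u`` — at the price that the procedure
is a lower bound: suffixes of long haplotypes can be missed.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .cv_engines import (
    HtrxConfig,
    HtrxResult,
    _strat,
    _subsample,
    stage2_evaluate,
    two_stage_cv,
)
from .dosage import HaplotypePanel, build_dosage_matrix
from .model_fit import PhenotypeTable
from .selection import CandidateModel, candidates_from_penalty, retain_best_M
from .templates import (
    FeatureSetSpec,
    canonical_sort,
    enumerate_templates,
    extend_templates,
    template_order,
)

__all__ = ["cumulative_stage1", "cumulative_htrx", "dispatch"]

logger = logging.getLogger(__name__)


def _initial_templates(
    u: int, positions: Sequence[int], spec: FeatureSetSpec | None
) -> list[str]:
    """All templates fixing only the given positions, padded to width u."""
    positions = sorted(positions)
    local = enumerate_templates(len(positions), spec)
    out = []
    for t in local:
        pat = ["X"] * u
        for p, c in zip(positions, t):
            pat[p] = c
        out.append("".join(pat))
    return canonical_sort(out)


def _apply_order_cap(templates: list[str], spec: FeatureSetSpec | None) -> list[str]:
    if spec is None or spec.max_order is None:
        return templates
    return [t for t in templates if template_order(t) <= spec.max_order]


def cumulative_stage1(
    panel: HaplotypePanel,
    pheno: PhenotypeTable,
    cfg: HtrxConfig,
    rng: np.random.Generator,
    spec: FeatureSetSpec | None = None,
    sample_idx: np.ndarray | None = None,
    snp_order: Sequence[int] | None = None,
) -> tuple[list[CandidateModel], list[int]]:
    """One stage-1 replicate of cumulative HTRX.

    On a fraction ``D`` of the samples: enumerate all templates on ``L``
    random SNPs, retain the best ``M`` by unpenalized forward regression,
    extend SNP-by-SNP (3M+2 candidates per step, pruned back to M), close
    with the last SNP unpruned, and select the best ``q`` candidate
    models by the configured penalty.  Returns the candidates and the
    instrumented design-matrix width at every fitting step.

    ``sample_idx`` and ``snp_order`` override the random subsample and
    SNP visit order (used for reproducibility checks).
    """
    u = panel.u
    if u <= cfg.L:
        raise ValueError("cumulative growth requires u > L; use two_stage_cv")
    if spec is not None and spec.htr_only:
        raise ValueError("HTR feature sets cannot be grown cumulatively")
    if sample_idx is None:
        sample_idx = _subsample(rng, pheno.n, cfg.D, _strat(pheno))
    if snp_order is None:
        snp_order = rng.permutation(u)
    snp_order = list(snp_order)
    sub_panel = panel.subset(sample_idx)
    sub_pheno = pheno.subset(sample_idx)
    widths: list[int] = []

    current = _initial_templates(u, snp_order[: cfg.L], spec)
    widths.append(len(current))
    F = build_dosage_matrix(sub_panel, current).to_numpy()
    retained = retain_best_M(F, current, sub_pheno, cfg.M)

    for j in snp_order[cfg.L : -1]:
        grown = _apply_order_cap(extend_templates(retained, int(j)), spec)
        widths.append(len(grown))
        F = build_dosage_matrix(sub_panel, grown).to_numpy()
        retained = retain_best_M(F, grown, sub_pheno, cfg.M)

    closing = _apply_order_cap(extend_templates(retained, int(snp_order[-1])), spec)
    widths.append(len(closing))
    F = build_dosage_matrix(sub_panel, closing).to_numpy()
    cands = candidates_from_penalty(F, closing, sub_pheno, cfg.penalty, q=cfg.q)
    return cands, widths


def cumulative_htrx(
    panel: HaplotypePanel,
    spec: FeatureSetSpec | None,
    pheno: PhenotypeTable,
    cfg: HtrxConfig,
) -> HtrxResult:
    """Cumulative HTRX: B replicates of bounded-width growth, then the
    two-stage validation/test rotation over the deduplicated candidates."""
    if cfg.family is not None and cfg.family != pheno.family:
        raise ValueError("config family disagrees with phenotype family")
    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(cfg.B + 1)
    candidates: list[CandidateModel] = []
    max_width = 0
    for b in range(cfg.B):
        rng = np.random.default_rng(streams[b])
        cands, widths = cumulative_stage1(panel, pheno, cfg, rng, spec)
        max_width = max(max_width, max(widths))
        for c in cands:
            candidates.append(
                CandidateModel(c.templates, c.penalty, c.criterion, source=b)
            )
        logger.info(
            "cumulative replicate %d: widths max %d, candidates %s",
            b,
            max(widths),
            [list(c.templates) for c in cands],
        )
    union = canonical_sort({t for c in candidates for t in c.templates})
    # stage 2 only needs dosage columns for templates that were proposed
    F = build_dosage_matrix(panel, union).to_numpy() if union else np.empty((pheno.n, 0))
    result = stage2_evaluate(
        F,
        union,
        pheno,
        candidates,
        cfg,
        np.random.default_rng(streams[-1]),
        algorithm="cumulative",
    )
    result.stage1_max_width = max_width
    return result


def dispatch(
    panel: HaplotypePanel,
    spec: FeatureSetSpec | None,
    pheno: PhenotypeTable,
    cfg: HtrxConfig,
    algorithm: str = "auto",
) -> HtrxResult:
    """Route a region to the appropriate engine.

    ``auto`` uses exhaustive two-stage CV for regions of at most
    ``max(6, cfg.L)`` SNPs and cumulative growth for longer ones; the
    other values force a specific engine (``two-stage`` stays feasible on
    longer regions when ``spec`` constrains the interaction order).
    """
    algorithm = algorithm.lower()
    threshold = max(6, cfg.L)
    if algorithm == "auto":
        algorithm = "two-stage" if panel.u <= threshold else "cumulative"
        logger.info("dispatch: u=%d -> %s", panel.u, algorithm)
    if algorithm == "two-stage":
        return two_stage_cv(panel, spec, pheno, cfg)
    if algorithm == "cumulative":
        return cumulative_htrx(panel, spec, pheno, cfg)
    raise ValueError(f"unknown algorithm {algorithm!r}")
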