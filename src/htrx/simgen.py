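"""Synthetic LD-block genotypes and phenotypes for testing every engine.

The generator emulates a GWAS-hit region with the features that make
haplotype learning hard in practice: strong LD, sparse large main
effects, weaker sparse interactions that mix SNPs with and without main
effects, an observed confounder correlated with the genetic structure,
and low power (a large error variance / rare binary outcome).

Genotypes come from a one-parameter latent-copy model: each haplotype
draws a latent allele Z ~ Bernoulli(allele_freq) and every SNP copies Z,
flipping independently with probability ``flip_prob``.  The closed-form
pairwise correlation between SNPs is

    corr = [f(1−ε)² + (1−f)ε² − p²] / (p(1−p)),   p = f(1−ε) + (1−f)ε,

which at the defaults f = 0.2, ε = 0.0035 gives ≈ 0.978 with an
alternative-allele frequency ≈ 0.20.

The phenotype linear predictor is

    f_i = β_G2·G_i2 + β_G4·G_i4 + β_H1·H_i1 + β_H2·H_i2 + β_C·C_i + λ

with H_1 the 'X0XX1X' and H_2 the '1XX0X1' template dosages, confounder
C = 0.5·G_2 − 0.8·G_4 (emitted as an observed covariate), λ = −4 and a
N(0, 4) error for the continuous outcome; the binary outcome is drawn
as Bernoulli(logistic(f_i)).  Effect sizes are specified in standard-
deviation units of each feature: a multiplier ``s`` realizes the
coefficient ``s / sd(feature)`` on the raw feature, i.e. a one-sd change
of the feature moves the linear predictor by ``s``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .dosage import HaplotypePanel, build_dosage_matrix
from .model_fit import PhenotypeTable

__all__ = [
    "SimParams",
    "ld_block_correlation",
    "simulate_ld_block",
    "simulate_phenotype",
    "simulate_dataset",
    "timing_fixture",
]


@dataclass
class SimParams:
    """Parameters of the LD-block simulation.

    ``main_effects`` maps 0-based SNP index to an effect multiplier in
    sd units; the defaults place 0.5-sd effects on the second and fourth
    SNPs, 0.3-sd effects on the two interaction templates, and a 1-sd
    effect on the confounder C = 0.5·G2 − 0.8·G4.
    """

    n: int = 100_000
    u: int = 6
    allele_freq: float = 0.2
    flip_prob: float = 0.0035
    main_effects: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 3: 0.5}
    )
    interactions: dict[str, float] = field(
        default_factory=lambda: {"X0XX1X": 0.3, "1XX0X1": 0.3}
    )
    confounder_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 3: -0.8}
    )
    confounder_effect: float = 1.0
    error_variance: float = 4.0
    intercept: float = -4.0
    family: str = "linear"
    ploidy: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.allele_freq < 1.0):
            raise ValueError("allele_freq must be in (0, 1)")
        if not (0.0 <= self.flip_prob < 0.5):
            raise ValueError("flip_prob must be in [0, 0.5)")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        for t in self.interactions:
            if len(t) != self.u:
                raise ValueError(f"interaction template {t!r} length != u={self.u}")


def ld_block_correlation(allele_freq: float, flip_prob: float) -> float:
    """Closed-form pairwise SNP correlation of the latent-copy model."""
    f, e = allele_freq, flip_prob
    p = f * (1 - e) + (1 - f) * e
    cov = f * (1 - e) ** 2 + (1 - f) * e**2 - p**2
    return cov / (p * (1 - p))


def simulate_ld_block(
    params: SimParams, rng: np.random.Generator | None = None
) -> HaplotypePanel:
    """Simulate phased haplotypes for one LD block.

    Each haplotype copy draws its own latent allele; diploid samples get
    two independent copies.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    shape = (params.n, params.ploidy)
    z = (rng.random(shape) < params.allele_freq).astype(np.uint8)
    flips = (rng.random(shape + (params.u,)) < params.flip_prob).astype(np.uint8)
    h = z[:, :, None] ^ flips
    return HaplotypePanel(h, [f"snp{j}" for j in range(params.u)])


def simulate_phenotype(
    panel: HaplotypePanel,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> PhenotypeTable:
    """Phenotype (and confounder covariate) for a simulated panel.

    Realized raw-scale coefficients are ``multiplier / sd(feature)``
    with the sd computed empirically on the generated sample; features
    enter centred so the intercept keeps its stated meaning.  Returns a
    :class:`PhenotypeTable` whose single covariate column is the
    confounder C; ``meta`` records the realized coefficients, the linear
    predictor and (for the binary family) the prevalence.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    g = panel.snp_dosage  # (n, u)
    n = panel.n
    f = np.full(n, params.intercept, dtype=float)
    realized: dict[str, float] = {}

    def add_term(name: str, x: np.ndarray, mult: float) -> None:
        sd = float(x.std())
        if sd == 0.0:
            warnings.warn(f"feature {name} has zero variance; term omitted")
            realized[name] = 0.0
            return
        coef = mult / sd
        realized[name] = coef
        f[:] += coef * (x - x.mean())

    for j, mult in params.main_effects.items():
        add_term(f"G{j + 1}", g[:, j], mult)
    if params.interactions:
        dos = build_dosage_matrix(panel, list(params.interactions))
        for t, mult in params.interactions.items():
            add_term(t, dos[t].to_numpy(), mult)
    c = np.zeros(n)
    for j, w in params.confounder_weights.items():
        c += w * g[:, j]
    add_term("C", c, params.confounder_effect)

    if params.family == "linear":
        y = f + rng.normal(0.0, np.sqrt(params.error_variance), size=n)
        meta = {"realized_coef": realized, "linear_predictor": f.copy()}
    elif params.family == "logistic":
        pi = expit(f)
        y = (rng.random(n) < pi).astype(float)
        meta = {
            "realized_coef": realized,
            "linear_predictor": f.copy(),
            "prevalence": float(y.mean()),
        }
    else:
        raise ValueError(f"unknown family {params.family!r}")
    return PhenotypeTable(
        y, covariates=c[:, None], family=params.family, meta=meta
    )


def simulate_dataset(
    params: SimParams,
) -> tuple[HaplotypePanel, PhenotypeTable]:
    """Panel plus phenotype from one seeded stream."""
    rng = np.random.default_rng(params.seed)
    panel = simulate_ld_block(params, rng)
    pheno = simulate_phenotype(panel, params, rng)
    return panel, pheno


def timing_fixture(
    n: int = 2000,
    u: int = 6,
    family: str = "linear",
    seed: int | None = None,
) -> tuple[HaplotypePanel, PhenotypeTable]:
    """Benchmark fixture: an LD block of ``u`` SNPs, 2000 samples and two
    fixed standard-normal covariates with nonzero effects.

    The causal structure of the 6-SNP design is kept (templates padded
    with 'X' for u > 6) so scaling runs exercise realistic signal.
    """
    if u < 6:
        raise ValueError("timing fixture requires u >= 6")
    pad = "X" * (u - 6)
    params = SimParams(
        n=n,
        u=u,
        interactions={"X0XX1X" + pad: 0.3, "1XX0X1" + pad: 0.3},
        family=family,
        seed=seed,
    )
    rng = np.random.default_rng(params.seed)
    panel = simulate_ld_block(params, rng)
    pheno = simulate_phenotype(panel, params, rng)
    covs = rng.standard_normal((n, 2))
    shift = 0.5 * covs[:, 0] - 0.5 * covs[:, 1]
    if family == "linear":
        y = pheno.y + shift
    else:
        pi = expit(pheno.meta["linear_predictor"] + shift)
        y = (rng.random(n) < pi).astype(float)
    return panel, PhenotypeTable(y, covariates=covs, family=family, meta=pheno.meta)
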