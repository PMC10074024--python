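# Methods

## The problem

A GWAS hit rarely identifies *which* variants in a high-LD block act on
the phenotype, whether a single tagging SNP is an adequate description,
or whether SNP–SNP interactions contribute. `htrx` addresses the simpler,
answerable question: how much out-of-sample variance in the phenotype is
explainable by haplotypes of the region — including non-contiguous ones —
beyond fixed covariates?

## Templates and dosages

A region of `u` biallelic SNPs defines templates: strings over
`{0, 1, X}` where `0`/`1` fix the reference/alternative allele and `X`
matches either. `1XX0` encodes an interaction between the first and
fourth SNP only; templates with no `X` reproduce classic haplotype trend
regression (HTR). A region yields `3**u − 1` templates (the all-`X`
pattern is the intercept and is excluded), of which only `2**u − 1` are
linearly independent given the intercept — the dosage of any template is
the sum of the dosages of the full haplotypes it matches. Per-sample
dosage is the fraction of haplotype copies matching the template:
`{0, 1}` for haploids, `{0, 0.5, 1}` for diploids. Rank deficiency is
therefore *expected*; fits use minimum-norm least squares and flag
degeneracy instead of failing.

Interaction order can be capped (`max_order`): the `SNP`, `2SNP_hap`,
`3SNP_hap`, … feature sets of size `sum(C(u,m)·2**m, m ≤ K)`. Capping
both speeds up the search and, empirically, avoids power loss — it is
rare for many SNPs to interact at once.

## Models and the score

Phenotypes are continuous (linear regression) or binary (logistic
regression via IRLS, tolerance 1e−8 on relative log-likelihood change,
at most 100 iterations, step-halving near separation; non-convergence or
|coefficient| > 50 marks the model degenerate rather than erroring —
degenerate candidates must lose in validation, not crash a sweep).
Covariates are always included and never penalized.

The score of a model on held-out data is the covariate-adjusted
out-of-sample R²:

* linear: `1 − RSS_full / RSS_cov`,
* logistic: `1 − ℓ_full / ℓ_cov` (a McFadden-style ratio of held-out
  log-likelihoods; test-fold probabilities are clipped at 1e−12 so
  overfit models get finite, very negative scores),

where the reference is an intercept+covariates model trained on the same
training data. Values below zero diagnose overfitting and are never
clamped. Information criteria use `AIC = 2m − 2ℓ`, `BIC = m·ln(n) − 2ℓ`
with `m` counting all mean parameters plus, for the linear family, the
error variance (the R `AIC`-for-`glm` convention; only criterion
*differences* matter for selection, so the convention affects nothing
but the printed values).

## Candidate generation (penalties)

* **AIC/BIC**: greedy forward regression. Linear-family steps are exact
  and computed by residualization (the gain of a candidate feature is
  its squared partial correlation with the current residual), which
  makes a step one matrix product. Logistic steps refit IRLS per
  candidate with warm starts; when more than 40 features remain, the
  candidates are pre-screened by Rao score statistic and only the top 40
  are exact-refit. The score statistic is asymptotically equivalent to
  the likelihood-ratio gain, so this screening is a numerical shortcut,
  not a different selector; with ≤ 40 features the step is exhaustive.
  The path stops when no addition improves the criterion. Ties break to
  the lowest canonical template (ascending order, then lexicographic
  with '0' < '1' < 'X') for determinism.
* **loglik** (used by cumulative retention): the same greedy path with
  no penalty, run for exactly `M` steps. When collinearity exhausts
  informative features before `M` (routine under strong LD, where the
  template space has low numerical rank), the remaining slots are filled
  with zero-gain features in canonical order; they are spanned by the
  kept set, so fits are unchanged and retention keeps exactly
  `min(M, p)` features, which keeps the growth lossless when `M` is
  large.
* **lasso**: an L1 path of 100 log-spaced penalties from the smallest
  all-zero penalty down to 1e−4 of it. Features are standardized
  internally for the path only. Intercept and covariates are exactly
  unpenalized: the linear family residualizes them out (Frisch–Waugh)
  and uses scikit-learn's coordinate-descent path; the logistic family
  uses a pathwise proximal-gradient (FISTA) solver with a penalty mask,
  because no available implementation penalizes a subset of columns.
  Distinct supports along the path are refit unpenalized and ranked by
  BIC, which puts all three penalties on a comparable footing.

"Best `q` candidate models" from a forward path means the `q` path
prefixes with the lowest criterion value; the empty prefix is a
legitimate candidate (under the null the correct answer is "nothing").

## Algorithms

* **Direct-Fit**: one unpenalized fit of all features on all data — the
  overfitting baseline. Its honest assessment is its k-fold CV score
  (train on k−1 folds, test on the held-out fold, average).
* **Direct CV**: per fold, penalized training on the other k−1 folds and
  a held-out test score. The per-fold feature sets form an ensemble, not
  one interpretable set.
* **Two-stage CV** (k ≥ 3): stage 1 runs `B` replicates, each
  subsampling a fraction `D` of the samples without replacement
  (stratified by case status for binary outcomes — rare outcomes
  otherwise produce degenerate replicates) and proposing its best `q`
  candidate sets under the penalty; the union is deduplicated to `z`
  candidates (identity = template set). Stage 2 splits the data into
  `k` folds; in iteration `i` the test fold is `i`, the validation fold
  is `(i+1) mod k`, and every candidate is refit without penalty on the
  remaining `k − 2` folds, so each fold serves each role exactly once.
  The winner maximizes mean validation R² (ties: fewest templates, then
  canonical order); the headline score is the mean of the winner's test
  values, which were never used to select it. Candidates that cannot be
  fit in a rotation contribute NaN and are averaged over the rotations
  where they fit.
* **Cumulative HTRX** (for u > 6): each replicate grows templates —
  exhaustive enumeration on `L` random SNPs, retain best `M`, then
  repeatedly extend by one unused SNP (`3M + 2` candidates: each
  retained pattern with '0'/'1'/'X' at the new position plus the two
  fresh single-SNP templates) and retain `M` again; the final SNP closes
  the set without pruning, then penalized selection picks `q`
  candidates. Stage 2 is identical to two-stage CV. The design width
  never exceeds `max(3**L − 1 (order-capped), 3M + 2)` and compute time
  grows linearly in `u`. SNP visit order is uniform without replacement
  per replicate (the neutral choice); the last unused SNP is forced.
  Because suffixes of long haplotypes can be missed, the result is a
  lower bound on the explainable variance.

Seed discipline: a master seed spawns one independent `SeedSequence`
stream per stage-1 replicate plus one for the fold split, so any single
replicate is reproducible in isolation.

## The synthetic generator

The generator emulates the regime that motivates the method: strong LD,
sparse large main effects, weaker sparse interactions, an observed
confounder correlated with genotype, and low power. Each haplotype draws
a latent allele `Z ~ Bernoulli(0.2)`; every SNP copies `Z` with an
independent flip probability ε = 0.0035. The closed form
`corr = [f(1−ε)² + (1−f)ε² − p²]/(p(1−p))`, `p = f(1−ε) + (1−f)ε`,
gives the pairwise SNP correlation; ε was calibrated analytically so the
defaults yield ≈ 0.978 with allele frequency ≈ 0.20. The default region
has six SNPs and haploid samples.

The linear predictor is
`f = β_G2·G2 + β_G4·G4 + β_H1·H1 + β_H2·H2 + β_C·C + λ` with
`H1 = dosage('X0XX1X')`, `H2 = dosage('1XX0X1')`,
`C = 0.5·G2 − 0.8·G4` (emitted as an observed covariate), `λ = −4`, and
error `N(0, 4)` for the continuous outcome; the binary outcome is
`Bernoulli(logistic(f))` (prevalence ≈ 2%: low power by design).

Effect multipliers (0.5 for the mains, 0.3 for the interactions, 1 for
the confounder) are *per standard deviation of the feature*: the
realized raw-scale coefficient is `multiplier / sd(feature)`, with the
sd computed empirically on the generated sample and features entering
centred. This standardized-effect reading is a deliberate design
choice: the interaction templates are rare (frequencies ≈ 3.5e−3 and
7e−4 under the LD model), so scaling the coefficient *down* by the sd
would shrink their variance contributions to ~1e−6 of the phenotype
variance and no method could detect them at any realistic sample size;
under the per-sd reading each stated effect contributes its multiplier
(in phenotype-sd units) and the qualitative behaviour the method is
built to exhibit — interactions matter, confounding is real, HTRX beats
HTR — is actually present in the data.

**What the generator does not emulate:** real LD blocks have multiple
common haplotypes and recombination structure (here a single latent
allele with rare copy errors produces essentially two common haplotypes
plus rare discordants); effect sizes are fixed rather than drawn;
genotyping error, missingness and imperfect phasing are absent. Passing
tests therefore demonstrate the machinery's correctness and its
qualitative behaviour under the stated regime, not performance on real
cohorts. One consequence worth knowing: under the latent-copy model two
rare templates can match *identical* sample sets (their symmetric
difference has probability O(ε²)), so the identity of a selected rare
template is only identifiable up to that equivalence class — the exact
pattern recovered can legitimately differ from the generating one while
the fit is the same.

## Problem sizes used in the test suite

Unit tests run in milliseconds on toy fixtures. The stochastic
behavioural checks use: generator calibration and BIC-path
stabilization at n = 100 000; null
centering over 50 replicates at n = 2000; overfitting ordering and
HTRX-vs-HTR over 10 seeds of logistic data at n = 20 000; template
recovery over 20 seeds of linear data at n = 50 000; cumulative width
instrumentation over 20 replicates at u = 12; and the runtime-scaling
exponent over u ∈ {8, 12, 16, 20} at n = 2000. These sizes are the
package's chosen trade-off between statistical resolution and a test
suite that completes in minutes.

## Known limitations

* Hard calls only: no genotype likelihoods or imputation dosages.
* No rare-template frequency filter is applied before selection;
  penalization and the validation stage are left to handle rare
  templates (`template_frequency` supports reporting them).
* Biallelic SNPs only; unphased heterozygotes are a hard error because
  template dosages are meaningless without phase.
* Inference on coefficients is not provided — the method's output is a
  template set and its out-of-sample R², not p-values.
* The two-stage score estimates the out-of-sample variance explained by
  the *selected* model; with tiny `n` or extreme class imbalance the
  validation step can select unstable candidates (stratification
  mitigates but does not remove this).
* The within-CV two-stage score is only approximately unbiased under a
  global null. Stage-1 candidates are generated on subsamples of the
  *full* data (future test folds included), and each fold's outcomes
  enter both the validation average that picks the winner and the test
  average that scores it. With very many candidate features (all 728
  templates of a six-SNP region) at n = 2000 this leaves a positive
  bias of roughly +0.001 in the null score — invisible in any single
  analysis but resolvable by a high-replication test: refitting the
  same selected winners and scoring them on independent fresh draws
  gives a slightly *negative* mean, as theory predicts for pure-noise
  models. Scores of that magnitude should be read as "nothing here".
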