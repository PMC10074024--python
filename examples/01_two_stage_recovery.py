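"""Two-stage CV on a simulated LD block: recover interacting templates.

Simulates 20,000 haploid samples over six SNPs in strong LD with two
main effects (SNPs 2 and 4), two haplotype interactions ('X0XX1X' and
'1XX0X1') and an observed confounder C = 0.5*G2 - 0.8*G4, then runs
two-stage CV with BIC penalization and the default k=10, B=10, D=0.5,
q=3.
"""

import htrx

params = htrx.SimParams(n=20_000, seed=7)
panel, pheno = htrx.simulate_dataset(params)
print(f"simulated {panel.n} haploid samples, {panel.u} SNPs")
print(f"realized coefficients: "
      f"{ {k: round(v, 3) for k, v in pheno.meta['realized_coef'].items()} }")

cfg = htrx.HtrxConfig(k=10, B=10, D=0.5, q=3, penalty="bic", seed=17)
result = htrx.two_stage_cv(panel, None, pheno, cfg)

print(f"\n{result.z} distinct candidate models entered stage 2")
print(f"winning template set: {list(result.winner)}")
print(f"mean out-of-sample R2: {result.mean_r2:.4f}")
print(f"per-fold test R2: {[round(float(v), 4) for v in result.fold_test_r2]}")
print("\nThe winner's templates name the SNPs (and allele combinations)")
print("that predict the phenotype beyond the confounder; the mean R2 is")
print("the honest out-of-sample variance they explain. Under the strong")
print("LD of this block, rare templates are identifiable only up to")
print("near-duplicates, so the exact patterns can vary across seeds.")
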