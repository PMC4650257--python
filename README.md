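# extremecc

Case–control association analysis for **extreme-phenotype (threshold-selected)
exome studies**, with the statistical machinery such a design needs end to
end:

- **Synthetic cohorts** under the additive polygenic liability-threshold
  model: a latent liability `L = Σ_j b_j (g_j − 2p_j) + e`, `e ~ N(0, 1−h²)`,
  with cases ascertained from the upper tail fraction `K_sel` (exact
  pool simulation, or the first-order allele-frequency tilt
  `p_case = p + b p(1−p) φ(T)/K` for extreme tails) and unselected controls.
- **Quality control**: sample call rate and heterozygosity filters, variant
  call rate, and a Hardy–Weinberg exact test (controls only).
- **Single-variant association**: covariate-adjusted linear score test
  (`χ²₁ = n·corr²` of residualized phenotype and dosage), minor-allele
  oriented effects, genomic-control λ, and conversion of a case–control
  effect to liability-scale variance explained.
- **Gene-collapsed rare-variant tests**: CMC-style burden, a SKAT-type
  variance-component kernel test with Beta(1,25) MAF weights and
  moment-matched mixture-of-χ² p-values, and the optimal burden/kernel
  combination over a ρ grid calibrated by phenotype permutation.
- **Heritability**: GCTA-form GRM, single-component REML on the observed 0/1
  scale (profiled in the GRM eigenbasis), a Haseman–Elston cross-check, and
  the ascertainment-corrected liability conversion
  `h²_liab = h²_obs · K²(1−K)² / (z² P(1−P))`.
- **The increaser/decreaser (I/D) ratio** — the allele-direction statistic:
  among LD-clumped variants passing a nominal threshold, the count whose
  minor allele is enriched in cases over the count enriched in controls, per
  MAF bin × p threshold cell, tested via
  `Z = (log₂(I/D)_obs − μ)/σ` against a phenotype-permutation null and
  `p = P(χ²₁ > Z²)`. A deficit of rare "increasers" is the signature of rare
  alleles being more often detrimental than beneficial to the trait.
- **Power** for threshold-selected designs from the noncentral χ²₁ of the
  allelic case/control frequency difference.

## Worked example

```python
import numpy as np
from extremecc import SimParams, simulate_cohort, association_scan, \
    lambda_gc, id_ratio_analysis

params = SimParams(n_cases=1000, n_controls=1000, n_variants=2000,
                   n_genes=200, h2_liability=0.20, n_causal=200,
                   selection_quantile=0.01, pi_detrimental=0.9, seed=7000)
cohort = simulate_cohort(params)          # cases = top 1% of liability
res = association_scan(cohort.genotypes, cohort.phenotypes)
print(round(lambda_gc(res.loc[res.testable & (res.maf > .01), "p_cc"]), 3))

table = id_ratio_analysis(cohort.genotypes, cohort.phenotypes,
                          n_perm=200, seed=0)
cell = table[(table.maf_bin == "(0,0.01]") & (table.p_threshold == 0.01)]
print(cell[["n_snps", "I", "D", "obs_log2", "exp_log2_mean", "z_score"]])
```

prints (this exact seed):

```
1.243
   n_snps  I   D  obs_log2  exp_log2_mean   z_score
0      21  6  15 -1.321928      -0.055456 -0.944434
```

λ > 1 reflects genuine polygenic signal under ascertainment (not confounding
— the permutation null absorbs it), and the rare MAF bin shows 6 increaser
vs 15 decreaser alleles (log₂ ratio −1.32 against a null expectation near
0): rare minor alleles are depleted in the high-tail cases, the direction a
90%-detrimental rare architecture should produce. A single cohort gives a
modest Z; the test suite shows the rare-bin Z is negative in 25/25
replicates of this architecture.

The same stages are available as composable CLI subcommands
(`extremecc simulate | qc | assoc | genetest | herit | idratio | power`)
that read and write VCF/TSV.

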