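# Methods

This note documents the models, estimators and numerical choices behind
`extremecc`, in the order the pipeline runs.

## The liability-threshold model and the synthetic cohorts

Everything downstream assumes a threshold-selected case–control design: a
latent standard-normal liability, cases drawn from its upper tail fraction
`K_sel`, controls unselected. The generator (`extremecc.simulate`) makes
that structure concrete:

- **Variants.** `n_variants` independent biallelic SNVs with minor-allele
  frequencies drawn uniformly within three classes — rare (0.001, 0.01),
  low-frequency (0.01, 0.05), common (0.05, 0.5) — mixed with weights
  (default 0.5 / 0.2 / 0.3, an exome-array-like rare-heavy spectrum).
  Variants cluster into genes laid contiguously along 22 chromosomes (gene
  territories ≤ 50 kb, spaced 0.2–2 Mb) so physical clumping windows are
  meaningful. Functional classes are multinomial (NonSynonymous-dominated,
  default 86%), with an independent damaging flag (default probability 0.3).
- **Effects.** `n_causal` variants share the liability variance equally,
  `q_j = h²/n_causal`, so the per-minor-allele effect is
  `b_j = sqrt(q_j / (2 p_j (1−p_j)))`. With `Σ q_j = h²`, `Var(L) = 1` holds
  in expectation and is *not* re-standardized after the draw. A rare causal
  minor allele is detrimental (negative `b_j`) with probability
  `pi_detrimental` (default 0.5 = no asymmetry; the I/D statistic's target
  regime sets it near 1); non-rare causal effects are symmetric.
- **Controls** are `binomial(2, p_j)` per variant (no LD by default — the
  direction statistic needs controllable LD, not realistic LD; a block-copy
  utility `add_ld_duplicate` plants known-r² pairs for clumping tests).
- **Cases** come in two ascertainment modes. *Pool* mode simulates
  `n_cases/K_sel` individuals and keeps the top `n_cases` by liability —
  exact, used whenever `K_sel ≥ 0.005`. *Tilt* mode draws case genotypes at
  the first-order shifted frequency `p_case = p + b p(1−p)·i`,
  `i = φ(T)/K_sel` the selection intensity — the only tractable route at
  extreme fractions such as the default `K_sel = 3×10⁻⁴` (a pool would need
  millions of individuals). The tilt is first-order in the effect; the
  second-order gap against exact integration grows with `q_j` and with
  decreasing MAF (about 1×10⁻³ at q = 0.0015, MAF 0.25, K = 0.01, and near
  8×10⁻³ by q = 0.005 at MAF 0.05). Frequencies pushed outside (0,1) are
  clipped, with a tolerance (`clip_tol`, default 0.02) beyond which the
  generator refuses and advises smaller per-variant `q_j`. Tilt-mode cases
  carry no realized liability value (reported as NaN).
- **Defaults** mirror the study design being emulated: 1409 cases / 3253
  controls, `K_sel = 3×10⁻⁴`, liability h² = 0.174 over 1000 causal
  variants among 20 000.
- **Seeds.** One master seed; per-stage generators are spawned
  deterministically via `numpy.random.SeedSequence`.

What passing tests on these cohorts do **not** show: robustness to real LD,
population stratification, genotyping error, or realistic site-frequency
spectra — none of which the generator emulates.

## Quality control

Samples first, then variants (the order is fixed and the filters are
idempotent on their own output): sample call rate < 0.95; sample
heterozygosity beyond 4 s.d. of the mean (computed over MAF > 0.01 variants
to stabilise the statistic); variant call rate < 0.99; Hardy–Weinberg exact
p < 10⁻⁴. The HWE test conditions on the observed allele counts and sums
the probabilities of all same-parity heterozygote counts no more probable
than the observed one; it is evaluated in controls only, since cases are
ascertained on phenotype and HWE can be legitimately distorted at trait
loci. Every removal is logged with unit, reason, value and threshold;
array-intensity/cluster columns are reserved but always NaN (no intensity
data flows through this pipeline).

## Single-variant association

The test is a covariate-adjusted linear score test: residualize the 0/1
status and the dosage on covariates plus an intercept, then
`χ²₁ = n·corr²(resid_y, resid_g)`; `beta = cov/var(resid_g)`. With no
covariates this is the Armitage trend test up to `n/(n−1)`. Treating binary
status linearly is deliberate — it is what the mixed-model association
packages this design is usually analysed with do, and the direction
statistic needs only (beta, p, MAF). A kinship mixed model is *not* fitted:
the synthetic cohorts have no cryptic structure by construction, and top
GRM eigenvectors can be supplied as covariates where confounder control is
wanted (this PC-adjusted score test is the package's one deliberate
methodological substitution for the mixed model). Effects are re-expressed
for the minor allele on the combined case+control frequency (which is
permutation-invariant — required for the permutation null); at frequency
exactly 0.5 the alt allele is the minor allele by convention. λ_GC is the
median association χ² over 0.4549.

A single variant's case–control effect converts to liability-scale variance
explained by solving the implied case/control frequencies from the linear
beta (or allelic OR) and the case fraction P, inverting the tilt relation
`p_case − p_ctrl = b·p_ctrl(1−p_ctrl)·i` for the liability effect b, and
returning `q = 2p(1−p)b²`; q is invariant to which allele is labelled
minor.

## Gene-collapsed rare-variant tests

Grouping schemes select rare (MAF < 0.01) qualifying variants per gene:
StopGain+ESS+NonSynonymous, StopGain+ESS+damaging-NS, or StopGain+ESS.
Burden is the CMC-style collapse: the per-sample count of rare minor
alleles, tested with the score test (allele counts, not a carrier
indicator; the multi-bin frequency pooling of the original CMC is collapsed
to the single rare bin). The kernel test is `Q = Σ_j w_j² S_j²` with
covariate-adjusted scores `S_j` and Beta(1,25) MAF-density weights (the
SKAT default; no weighting is prescribed by the design itself), with the
null `Σ λ_k χ²₁` tail by moment matching (Liu-style; exact for a single
eigenvalue, so a one-variant gene reproduces the score test). The optimal
combination interpolates `Q_ρ = (1−ρ)Q_kernel + ρQ_burden` over
ρ ∈ {0, 0.01, 0.04, 0.09, 0.25, 0.5, 1}, where the ρ = 1 axis is the
*weighted*-score burden; the minimum p over the grid is calibrated by
phenotype permutation (default 2000 permutations, `(1+#better)/(n+1)`)
rather than the one-dimensional analytic tail integral — exact at desk
scale, and the endpoints remain analytically checked. A single-element grid
needs no multiplicity correction and returns the analytic p.

## Heritability

GRM: `A_ab = (1/m) Σ_j (g_aj−2p_j)(g_bj−2p_j)/(2p_j(1−p_j))` (the
centered-scaled GCTA form; per-SNP LD weighting is pointless on LD-free
simulated variants), missing dosages mean-imputed only here. REML profiles
the single-component log-likelihood over h² ∈ [0,1) in the GRM eigenbasis
(one bounded scalar optimization; σ²_p profiled out), with the standard
error from the numerical curvature at the optimum; boundary estimates are
flagged as non-converged. A Haseman–Elston regression (phenotype
cross-products on GRM off-diagonals) is reported alongside as a moment
cross-check. The observed-scale estimate converts to the liability scale by
`K²(1−K)²/(z²P(1−P))` with K the prevalence/selection fraction, P the
sample case fraction, z the normal density at the threshold; the s.e.
scales by the same multiplier (delta method, K and P fixed); values over 1
are clamped and flagged.

## The increaser/decreaser statistic

Pipeline per cohort: score-test scan → greedy LD clumping (ascending p,
ties by chromosome then position; an index variant removes all variants on
the same chromosome within ±1 Mb with dosage r² > 0.1) → per-cell counts
over MAF bins {(0,0.01], (0.01,0.05], (0.05,0.15], (0.15,0.5]} (lower-open,
upper-closed) × thresholds p < {0.01, 0.001} (strict). I counts oriented
beta > 0, D beta < 0; beta exactly 0 is counted in `n_snps` but in neither
direction (a measure-zero tie rule stated for determinism). The observed
`log₂(I/D)` is compared with the mean μ and s.d. σ of the same quantity
over phenotype permutations (case count preserved exactly; MAF,
orientation and the r² adjacency are permutation-invariant and computed
once), giving `Z = (obs−μ)/σ` and `p = P(χ²₁ > Z²)`. Zero counts use a
+0.5/+0.5 continuity correction, flagged per cell and per permutation;
cells with I = D = 0 contribute no statistic (dropped permutations are
counted); a permutation s.d. at floating-point noise level (≤ 10⁻⁹) is
treated as a degenerate null and no Z is reported. The displayed expected
ratio is `2^μ` (the geometric mean of permuted ratios); μ itself is also
emitted. On sparse cells the χ²₁ p is conservative — the log₂ ratio is
heavily discrete — which the null-calibration test quantifies.

## Power

For a variant explaining q of liability variance, the case minor-allele
frequency comes either from the mean-shift (`m_case = φ(T)/K`, or an
explicit standardized case-mean override) or from exact genotype-stratified
tail integration (`P(case|g) = Φ̄((T − b(g−2p))/√(1−q))`, Bayes-inverted).
Power is the upper tail of noncentral χ²₁ beyond the central critical value
at α, with `ncp = (p_case − p)²/(p̄(1−p̄)(1/(2n₁)+1/(2n₀)))`, p̄ the
sample-size-weighted mean — the standard pooled two-proportion form, which
makes power only *approximately* MAF-invariant at fixed q (the shift enters
p̄). At the emulated design (q = 0.0015, α = 10⁻⁷, 1409/3253) the
truncated-normal case mean gives materially less than 80% power; a
standardized case-group mean override of 5.07 (the realized mean of a
cohort whose trait mean sits ~5 s.d. above the population) brings it near
0.8 — both regimes are exposed rather than asserting one.

## Problem sizes used by the test suite

The calibration and recovery checks run at sizes chosen to make their
statistical claims testable on one CPU: null calibration over 50 cohorts of
1000 samples × 2000 variants with 200 permutations each (I/D p-values
pooled over all defined cells; λ_GC asserted on the mean over cohorts);
heritability recovery over 9 pool-ascertained cohorts of 2000 samples ×
3000 variants; the detrimental-architecture signature over 25 cohorts of
2000 samples × 2000 variants. Brute-force oracles (label permutation for
burden/kernel/score tests, exhaustive-search clumping, full HWE
enumeration) run on toys of 40–300 samples. Discrete statistics are
compared with permutation oracles via the strict/inclusive tail bracket
(the gap between `P(T > t)` and `P(T ≥ t)` is tie mass, which an asymptotic
p cannot resolve).

## Known limitations

- No mixed-model kinship correction; confounder control is PC-based.
- Analytic SKAT-type tail probabilities use moment matching, not exact
  integration; accuracy in the far tail (p ≪ 10⁻⁴) is approximate.
- The liability conversion is exact only in the small-effect limit; large
  observed-scale estimates can overshoot (clamped, flagged).
- The generator omits LD, stratification and genotyping error, so the
  pipeline's robustness to those is untested by construction.
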