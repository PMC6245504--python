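# Methods

This note documents the models implemented in `gxetwin`, the synthetic
cohort the package is verified against, the calibration algebra, and the
numerical choices. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The scientific design

Three related designs triangulate whether child BMI evokes parental feeding
behaviour:

1. **Between-family (GPS) design.** A child's genome-wide polygenic score
   for BMI indexes genetic propensity that cannot be caused by parental
   behaviour; a correlation between the child's score and a parental
   behaviour is therefore evidence of gene–environment correlation.
2. **Within-family (fixed-effects) design.** Regressing a feeding practice
   on the score with one intercept per DZ family removes *all* shared
   family influences (parental genotype, household environment); only
   within-pair score differences identify β.
3. **Twin (ACE) design.** MZ pairs share all segregating variants, DZ pairs
   half on average, and both share their family environment; comparing
   within- and cross-trait twin covariances decomposes variance into
   additive-genetic (A), shared-environment (C) and non-shared (E) parts
   and gives the aetiological correlations r_A, r_C, r_E between traits.
   MZ-discordance regression isolates the E-only pathway.

## 2. Correlated-factors ACE model

For p traits with path coefficients a_i, c_i, e_i and correlation matrices
R_A, R_C, R_E (unit diagonal, positive definite), define A = D_a R_A D_a
(similarly C, E, with D_a = diag(a)). The expected 2p × 2p covariance of a
twin pair is

    [[A + C + E,  wA + C], [wA + C,  A + C + E]],   w = 1 (MZ), 0.5 (DZ)

with trait means equated across twins and zygosity groups. This matrix is
positive definite for any e_i > 0, because Σ ± Σ_cross reduce to E + (1∓w)A
and 2C + (1+w)A + E.

**Likelihood.** −2 log L is the sum over pairs of the multivariate-normal
density; pairs with partial missingness contribute the marginal density of
their observed subset (full-information ML). Rows are grouped by
missingness pattern and reduced to (n, mean, scatter) sufficient
statistics, so one evaluation costs a handful of p-dimensional Cholesky
solves regardless of sample size. A listwise switch is not needed for the
structured models; the saturated model uses listwise-complete per-group
MLEs (closed form), which coincides with FIML on complete data — the only
case in which we report saturated-vs-ACE likelihood ratios.

**Parameterization.** Squared paths are optimized as log-variances
(positivity for free); correlation matrices through row-normalized Cholesky
factors, an unconstrained map onto exactly the positive-definite unit-
diagonal matrices. Standardized proportions a²/(a²+c²+e²) and the
correlations are computed after the fit. Sub-models (AE, CE, E) drop the
corresponding blocks.

**Optimization.** L-BFGS-B with numerical gradients, bounds ±20 on the log
and Cholesky parameters; multi-start (default 5) from a Falconer-style
moment estimate (A₀ = 2(r_MZ − r_DZ), C₀ = r_MZ − A₀, phenotypic
correlations shrunk by ½ as starting aetiological correlations) plus seeded
N(0, 0.3) jitters. Convergence requires a finite optimum and best-start
agreement within 1e-4 in −2 log L (reported in `diagnostics`).

**Profile CIs.** The 95% bound is where the re-optimized −2 log L exceeds
its minimum by χ²₁(0.95) = 3.84. The constrained inner problem (SLSQP with
an equality constraint on the reported quantity — a standardized proportion
or an aetiological correlation) is warm-started along an expanding search,
and the crossing is localised by plain bisection (tolerance 1e-3), which is
robust to the slight path dependence of warm-started re-optimization.
Bounds that never cross inside the parameter domain ([0,1] or [−1,1]) are
returned censored at the domain edge. Coverage is verified empirically in
the test suite: 200 replicates of a univariate design at 300 pairs per
group, at an interior parameter point (A = 0.5, C = 0.3) where boundary
truncation does not distort the sampling distribution.

**Degrees of freedom** are counted as (number of observed data values) −
(free parameters), the convention of mainstream SEM software; AIC =
−2 log L + 2·ep.

## 3. The synthetic cohort generator

The generator produces the exact statistical structure the analyses assume;
its defaults are the study conditions the package is verified against
(1,636 MZ, 1,441 same-sex DZ, 1,298 opposite-sex DZ pairs, 4,445 unrelated
singletons; children ~9.9 ± 0.9 years).

**Genotypes.** SNPs sit in LD blocks (default 5 SNPs sharing one allele
frequency ~U(0.1, 0.9)); within a block each haplotype copies the anchor
allele with probability φ = √r² (default r² = 0.25), giving exact control
of pairwise r². Blocks are 500 kb apart round-robin across 22 chromosomes,
so the 250 kb clumping window spans exactly one block. Parents draw
haplotypes from the population model; children receive one whole haplotype
per parent per block (free recombination between blocks, none within, so
LD is preserved across generations); MZ twins duplicate one child, DZ
twins are independent transmissions. MZ genotype identity, DZ sharing of
0.5 and parent–child sharing of 0.5 all *emerge* from this mechanism.

**Summary statistics.** Causal SNPs (default 1,000) are block anchors with
equal-magnitude, random-sign effects scaled so the true typed score has
unit variance; the fabricated discovery GWAS reports observed β = true β +
N(0, SE²) with SE = 1/√(2f(1−f)·N) at N = 339,224, and Wald p-values.
Non-causal SNPs are pure noise (LD-induced marginal effects are not
modelled in the summary statistics; LD enters through the dosages, which
is what clumping consumes).

**Latent factors.** Additive factors use the parental-midpoint
construction: each parent draws N(0,1), the child gets (m+f)/2 + N(0,½);
MZ co-twins share the segregation draw. One mechanism yields MZ/DZ/parent–
child additive correlations of 1 / 0.5 / 0.5 simultaneously. The BMI
additive factor is λ·G* + √(1−λ²)·U, where G* is the standardized true
typed score computed from the transmitted genotypes and U an untyped
midpoint factor; cross-trait structure comes from a Cholesky of R_A whose
first variable is the BMI factor, so the tagging survives the mixing.
Shared factors are one N(0, R_C) draw per family, non-shared factors one
N(0, R_E) draw per individual; trait = √A·a + √C·c + √E·e.

**Raw measurements.** The BMI-SDS trait is back-transformed to raw BMI
through a synthetic LMS reference (shipped, clearly synthetic: smooth
curves with plausible medians/skew for ages 7–13); height-SDS is an
independent N(0,1) and weight = BMI·height². The preparation stage
recovers BMI-SDS exactly up to the age/sex residualization (which removes
only chance covariance, ~0.1% at analysis n). The reference CSV carries a
`measure` column (bmi/height/weight) so the ±5 SD exclusion rule can use
reference-based SDS for all three measures; files without it are read as
BMI-only and height/weight rules fall back to sample z-scores.

**Likert items.** Item deviations are drawn zero-sum around the trait, so
the continuous composite equals the trait exactly; their magnitude is set
so that, after the analytic equal-probability 5-level discretization
attenuation ρ_d ≈ 0.942 per item, the observed inter-item correlation hits
the value implied by the target alpha (0.78 for 6 restriction items, 0.61
for 4 pressure items). Discretization still costs ≈ 2% of the correlation
between the item composite and the underlying trait; consequently
scale-trait estimates from the full item pipeline are attenuated by ≈ 2–4%
relative to the generating values, and the twin-model recovery studies use
the continuous trait scores drawn from the same generating model. Item
error cannot be nested inside the trait's E component: the unreliability
implied by alpha = 0.78 (22% of composite variance) exceeds the trait's
total non-shared variance (14%), so item noise is modelled as
trait-orthogonal indicator noise instead — a real-data feature (twin-E
smaller than 1−alpha) that the generator reproduces by construction.

**Reporting parent.** One parent (3% fathers) reports; their BMI phenotype
is √h²_p · (own additive BMI value) + noise, log-normally mapped to raw
height/weight. Gender correction reduces to residualization on parent sex.

## 4. Calibration (all closed-form)

Targets: GPS→BMI correlation 0.20, parent–child BMI correlation 0.26,
alphas 0.78/0.61, phenotypic correlations 0.19 / −0.24 / 0.15, and the
reported r_A (0.28, −0.48) and r_E (0.20, −0.29) entries.

- **λ (GPS tagging):** corr(measured GPS, BMI) = λ·κ·√h²_BMI, where κ is
  the analytic attenuation of the measured score relative to the true
  typed score — truncated-normal moments for weight-estimation noise and
  p < 0.001 selection on causal SNPs, plus the variance contributed by
  null SNPs passing the threshold. λ = 0.20/(√0.78·κ). κ depends only on
  (n_causal, n_snps, discovery N, pT) and is ≈ 0.998 at the defaults; it
  is recomputed automatically when the panel design changes.
- **parent h²:** corr = √h²_p · 0.5 · √h²_BMI ⇒ h²_p ≈ 0.35. This is a
  *reporting-parent effective heritability* absorbing self-report error
  and assortative effects, not a claim about adult BMI heritability.
- **Inter-item correlations:** inversion of standardized alpha,
  r̄ = α/(k−(k−1)α), then divided by ρ_d² for the discretized items.
- **Unreported aetiological correlations:** the two r_C entries involving
  BMI are solved from the printed phenotypic correlations given the fitted
  variance components and the printed r_A/r_E entries; the
  restriction–pressure cell is unreported in all three matrices, so a
  single shared value ρ ≈ 0.151 (solving r_P = 0.15) is used for r_A, r_C
  and r_E there — one equation cannot identify three unknowns, and a
  common value is the least-structured choice that preserves every printed
  observable. All calibrated matrices are checked positive semi-definite;
  infeasible targets raise a `CalibrationError` naming the violated bound.
- **BMI variance components:** A = 0.78 is reported directly; C = 0.10 and
  E = 0.12 complete the triple at values consistent with late-childhood
  twin literature.

## 5. Polygenic-score stage

Clumping is greedy in ascending p (ties broken by chromosome, position,
SNP id, so the result is invariant to input row order): a SNP is kept
unless an already-kept SNP on the same chromosome within 250 kb has
r² > 0.1, with r² computed from the analysis dosages (complete pairs when
dosages contain missing values; a standardized SNP-major matrix otherwise).
Scores sum β × A1-allele dosage over kept SNPs with p ≤ pT; dosages counted
on the other allele are flipped (2−d), unresolvable alleles raise an error
listing the SNPs, and missing dosages are mean-imputed as 2·freq. Genotype
PCA filters MAF > 0.05, LD-prunes at r² > 0.1 in position order, and takes
randomized-SVD components scaled to unit variance; adjustment returns
z-standardized residuals of the score on the components (and optional batch
dummies), with a pseudo-inverse fallback and warning for collinear designs.

## 6. Problem sizes

Chosen as the package's own desk-scale study designs:

- Parent–child score correlation: 2,000 unlinked SNPs, 10,000 families.
- GPS association study: 50 replicate unrelated cohorts of n = 4,445 with
  a 6,000-SNP / 300-causal panel (λ recalibrated for that design; the
  estimand is invariant to panel size). GPS→BMI uses the first 20
  replicates; the feeding-practice regressions subsample to the reported
  analysis sizes (4,255 / 4,315). The full 20,000-SNP default panel is
  exercised in the test suite's single-cohort β(GPS→BMI) check.
- Twin recovery: acceptance reports the mean of 3 paper-scale cohorts
  (1,636 MZ + 2,739 DZ pairs each); the test suite additionally checks the
  mean of 50 reduced-n replicates (600 pairs/group) within ±0.02.
- CI coverage: 200 replicates, univariate, 300 pairs per group.

## 7. What passing tests do and do not show

The generator emulates: Mendelian transmission and block LD; a trivariate
ACE architecture at the fitted values; a polygenic score tagging the
calibrated share of additive variance; Likert measurement with target
reliabilities; a correlated reporting parent. It deliberately omits:
realistic human LD maps and allele-frequency spectra, LD-aware marginal
effects in the summary statistics, assortative mating, sex-limitation of
variance components, population stratification (the PCA stage therefore
removes only noise in simulated data, though its machinery is exercised),
genotyping batch structure, longitudinal BMI, and informative missingness.
Parameter recovery here shows the estimators are correct and calibrated
under the model's assumptions; it cannot show robustness to violations of
those assumptions in real cohort data.

## 8. Other numerical choices

- LMS lookup interpolates L, M, S linearly between bracketing ages and
  errors outside the table's age span; the |L| < 1e-7 log branch makes the
  transform continuous at L = 0.
- Composite scores require ≥ 4 of 6 (restriction) / ≥ 3 of 4 (pressure)
  answered items; responses outside 1..5 are rejected.
- Fixed-effects inference uses df = n − k − 1 (k families) and counts all
  family intercepts in the model adjusted R²; incomplete families are
  dropped whole. Variables are z-scored on the analysis sample *before*
  demeaning so within- and between-family β are on the same scale.
- The "unrelated individuals" sample is the singleton families when
  present, otherwise twin 1 of each pair (configurable).
- All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning; identical config + seed gives
  byte-identical cohort files and reports.
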