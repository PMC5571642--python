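# Methods

## Model

For each of R quantitative traits measured on N subjects, the marginal
model is a single-kernel linear mixed model

    yʳ = αʳ + x ηʳ + gˢ βʳ + zʳ + εʳ,
    zʳ ~ N(0, σ_g² K),   εʳ ~ N(0, σ² I),

with K the genetic relationship matrix and x optional fixed covariates
(by default the intercept plus the 10 leading genotype principal
components; PCs sharpen the adjustment for population structure that
the GRM alone captures imperfectly). The pleiotropy null hypothesis for
SNP s is that every βʳ is zero; it is tested by combining the R
marginal Wald p-values with the Fisher statistic ξₛ = Σᵣ −2 log p_{rs}
and referring ξₛ to a moment-matched gamma distribution.

Key assumptions: traits are continuous and (conditionally) Gaussian
with a common exchangeable-style residual dependence captured by the
pairwise correlations ρ_{rr'}; one SNP is tested at a time with
additive allele coding; the GRM is estimated from all available SNPs
including the tested one.

The cross-trait covariance of two traits contains both a genetic term
(relatedness) and the residual term ρ_{rr'} σ² I. Only ρ_{rr'} enters
step 2; the genetic cross-trait correlation is deliberately unmodeled —
the random effect zʳ absorbs relatedness within each marginal model, so
the combination step only needs the correlation that survives in the
conditional residuals.

## Step 1: spectral REML and plug-in Wald tests

With a single GRM, REML reduces to a 1-D problem in λ = σ_g²/σ². After
one symmetric eigendecomposition K = U L Uᵀ, data are rotated by Uᵀ and
the restricted log-likelihood at any λ costs O(N p²):

    ℓ_R(λ) ∝ −½[(N−p) log σ̂²(λ) + Σᵢ log(λlᵢ+1) + log|XᵀH⁻¹X|],
    σ̂²(λ) = rᵀH⁻¹r/(N−p),  H = λK + I.

The optimum is located on a 33-point log-spaced grid over
λ ∈ [10⁻⁶, 10⁶] and polished by bounded scalar minimization inside the
bracketing grid interval; exact ties resolve toward the smaller λ. The
σ_g² = 0 boundary is admissible; σ̂² is floored at 10⁻¹² · Var(y) so a
perfectly fitting design does not produce a zero variance. Small
negative GRM eigenvalues (numerical) are clipped at zero before use.

Each SNP is tested by generalized least squares of [X, g] under the
null-fit V̂ = σ̂_g² K + σ̂² I — variance components are *not* refitted
per SNP. In the rotated basis this is a weighted regression with
weights 1/(σ̂_g² lᵢ + σ̂²), vectorized over SNP blocks. A consistency
check in the test suite confirms the plug-in and the per-SNP-refit
p-values agree in rejection decision for ≥95% of null SNPs.

Conditional residuals ε̂ = y − Xb̂ − ẑ (BLUP subtracted,
ẑ = σ̂_g² K V̂⁻¹(y − Xb̂)) provide the residual-correlation estimate:
ρ̂ is their pairwise Pearson correlation matrix, computed once per
analysis from the null fits.

## Step 2: the gamma null

Moment matching gives kθ = 2R and
kθ² = 4R + Σ_{r≠r'} cov(−2 log p_r, −2 log p_r'), where the sum runs
over ordered pairs (each unordered pair counts twice — required for the
R = 2, ρ = 1 case to reproduce the duplicated-p limit Gamma(≈1, ≈4)).
Each covariance term is the degree-5 polynomial in ρ² with coefficients
(3.9081, 0.0313, 0.1022, −0.1378, 0.0941) minus the finite-sample
correction (c₁/N)(1−ρ²)², N being the number of analyzed subjects after
QC (negligible for N ≥ 500 but retained). ρ̂ entries are clipped to
[−1, 1] only as a guard against rounding noise; the polynomial is
finite on the whole interval, and evaluating it at exactly ±1 is what
makes the duplicated-trait reduction exact. If the matched variance
were non-positive (unreachable for valid correlation matrices at
N ≥ 10) the code fails loudly rather than silently falling back to
χ²_{2R}. One global gamma null serves all SNPs, since ρ̂ and N are
SNP-independent.

Upper tails use the regularized incomplete gamma; a log-scale tail is
available and switches to an asymptotic continued-series expansion when
the survival probability underflows double precision.

### The quadrature oracle

`exact_cov_oracle` computes cov(−2 log p₁, −2 log p₂) independently of
the polynomial: (Z₁, Z₂) standard bivariate normal with correlation ρ,
p_j = 2Φ(−|Z_j|), E[−2 log p] = 2 exactly, and E[g(Z₁)g(Z₂)] evaluated
by composite Gauss–Legendre quadrature on the positive quadrant (where
the folded integrand is smooth), with panels dense enough to resolve
the diagonal density ridge up to |ρ| = 0.999. Agreement with an
adaptive 2-D integrator is ~10⁻¹³; node-doubling changes results by
<10⁻⁸.

Measured with this oracle, the polynomial's maximum absolute error over
ρ = 0.00(0.01)0.90 is 1.14×10⁻⁴, attained near ρ ≈ 0.85; on the coarser
ρ = 0.0(0.1)0.9 grid the maximum is 6.4×10⁻⁵. Extrapolating to ρ = 1
the polynomial gives 3.9979 against the exact limit 4 (Var(χ²₂)).

## Simulators

**Genotypes.** Two ancestral populations receive independent
Uniform(0.1, 0.9) reference-allele frequencies per SNP. Founder parents
are drawn Binomial(2, p) within their population (HWE); admixed designs
assign parent pairs to Pop I×I, Pop II×II and Pop I×II in equal thirds
(remainders in that fixed order). Children receive one allele per
parent per SNP (alleles exchangeable — a parent of dosage d transmits
the reference allele with probability d/2; no phase is tracked, since
SNPs are simulated unlinked). The analysis sample is children only:
1000×1 for independent designs, 250×4 full sibs for related designs.
Not modeled: linkage disequilibrium, mutation, multi-generation
pedigrees, X chromosome, missing simulated genotypes — so passing tests
speak to population/family structure handling, not to LD-induced
confounding or call-rate artifacts in real data.

**Phenotypes.** y_i ~ MVN(μ(g_i), Σ) with μ_r = (g_i − 1)e_r (so
genotype AA shifts by −e, AB by 0, BB by +e at the single causal SNP,
default index 0) and Σ exchangeable with unit diagonal and common
off-diagonal ρ (positive definite for −1/(R−1) < ρ < 1; negative ρ is
accepted but excluded from the shipped study grids). No polygenic
background enters the phenotype model; a separate helper simulates
y = z + ε with z ~ N(0, σ_g² K) for variance-component recovery checks
only.

## Simulation studies and problem sizes

Shipped defaults are desk scale: 200 replicates and S = 2000 background
SNPs per cohort, with a pool of 10 pre-simulated cohorts per scenario
whose GRM eigendecompositions are reused across replicates (phenotypes
are redrawn every replicate). Study-scale settings (1000 replicates,
S = 10 000) are ordinary configuration values. Study grids: correlation
accuracy uses ρ ∈ {0, 0.3, 0.6, 0.9} × e ∈ {0, 0.5, 1} with R = 2;
type-I/power uses ρ ∈ {0, 0.4, 0.8} × e ∈ {0, 0.1, 0.2} with R = 4
(marginal power reported for trait 1; per replicate only the causal SNP
is tested, while the GRM uses all SNPs); the unequal-effect grid uses
e-vectors (0.1,0.1,0.1,0.1), (0.05,0.1,0.15,0.2), (0.15,0.15,0.15,0.15)
at ρ ∈ {0.1, 0.5} on the related admixed design. All runs are exactly
reproducible from (grid, seed) via spawned seed sequences.

## Known limitations

* **Gamma body error at high ρ.** Matching two moments controls the
  rejection rate at conventional α well (empirical size stays inside
  the 95% binomial band in the calibration study), but the p-value
  distribution's *body* deviates from uniform as trait correlation
  grows: with exact normal scores and the true correlation matrix the
  KS distance is ≈0.03 at ρ = 0.4 and ≈0.08 at ρ = 0.8 (R = 4). A KS
  test on thousands of null p-values therefore rejects uniformity at
  high ρ even for a perfect implementation. Users should treat the
  combined p-value as accurate for screening at small α rather than as
  exactly uniform under the null.
* **Polynomial accuracy.** The covariance polynomial is accurate to
  ~10⁻⁴ on ρ ∈ [0, 0.90] (see above) and degrades toward ρ = 1; the
  fixed published coefficients are shipped as-is, and the oracle exists
  to quantify, not refit, them.
* **Single-draw calibration runs.** Testing many null SNPs against one
  phenotype draw makes the resulting p-values exchangeable but not
  independent; batch-level shifts inflate the variability of KS/size
  summaries relative to their nominal sampling distributions.
* Exchangeable Σ, continuous traits, one causal SNP, no covariate-driven
  phenotype means; binary/ordinal traits and phenotype imputation are
  out of scope. Relationship inference and genotype QC beyond
  MAF/exact-HWE/missingness filters are left to dedicated tools.
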