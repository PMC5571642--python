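# mvfisher

Two-step multivariate genome-wide association testing for **correlated
quantitative phenotypes** measured on **related and/or admixed**
subjects — a pleiotropy test that combines per-trait mixed-model GWAS
p-values with a dependence-calibrated Fisher statistic.

## The problem and the method

Complex traits often come in correlated bundles (e.g. several alcohol-use
phenotypes), and a variant that influences the bundle may never reach
significance in any single-trait scan. Testing
H₀: β₁ = … = β_R = 0 jointly is more powerful, but two sources of
dependence must be handled: the correlation between traits, and the
genetic relatedness / population structure between subjects.

**Step 1 — marginal mixed-model scans.** Each trait *r* is modeled as

    yʳ = αʳ + x ηʳ + gˢ βʳ + zʳ + εʳ,    zʳ ~ N(0, σ_g² K),  εʳ ~ N(0, σ² I)

where **K** is the genetic relationship matrix estimated from all SNPs
(standardized-genotype estimator) and **x** holds the leading genotype
principal components and any other covariates. Variance components are
estimated once per trait by spectral REML under the null (no SNP); every
SNP is then tested with a 1-df Wald χ² whose variance plugs in the null
V̂ = σ̂_g² K + σ̂² I (O(N) per SNP after one eigendecomposition).

**Step 2 — dependence-calibrated Fisher combination.** Per SNP *s*,

    ξₛ = Σ_{r=1}^R −2 log p_{rs}.

Under independence ξₛ ~ χ²_{2R}; under trait correlation it is
approximated by Gamma(k, θ) with moments matched as

    kθ = 2R,
    kθ² = 4R + Σ_{r≠r'} cov(−2 log p_{rs}, −2 log p_{r's}),

where each covariance is evaluated from the residual trait correlation
ρ̂_{rr'} (Pearson correlation of the conditional residuals
ε̂ʳ = y − Xb̂ − ẑ) via the polynomial approximation

    cov ≈ Σ_{l=1}^5 c_l ρ^{2l} − (c₁/N)(1 − ρ²)²,

with c = (3.9081, 0.0313, 0.1022, −0.1378, 0.0941). A high-precision
quadrature oracle for the exact covariance is included and used to
validate the polynomial.

The package also ships the pedigree/admixture genotype simulator (two
ancestral populations with Uniform(0.1, 0.9) allele frequencies,
founder parents in three origin mixes, Mendelian gene dropping into
1000×1 or 250×4-sib designs), the multivariate-normal phenotype
simulator, and scripted simulation studies (correlation-estimator
accuracy, type-I error/power, unequal effect sizes).

## Worked example

Simulate a related admixed cohort (250 families × 4 sibs, 2000 SNPs)
with four traits, residual correlation ρ = 0.4 and a causal SNP of
effect e = 0.2, then run the full two-step analysis:

```bash
$ mvfisher simulate --scenario admixed-related --n-snps 2000 --n-traits 4 \
      --effect-size 0.2 --rho 0.4 --seed 42 --out cohort
wrote cohort.bed/.bim/.fam and cohort.pheno.tsv (1000 subjects, 2000 SNPs, 4 traits)

$ mvfisher gwas --bfile cohort --pheno cohort.pheno.tsv --out results
analyzed 1000 subjects, 1861 SNPs, 4 traits; gamma null k=2.7564 theta=2.9023; 0 SNPs below 1e-06
```

QC removed 139 SNPs (exact-HWE filter — expected in an admixed sample),
leaving 1861. The estimated residual-correlation matrix has
off-diagonals near the simulated 0.4 (0.37–0.42, see `results.log`),
giving a gamma null with k ≈ 2.76, θ ≈ 2.90 — wider than the χ²₈ that
independent traits would give (k = 4, θ = 2), exactly the correction
that keeps the combined test calibrated.

`results.combined.tsv` holds per-SNP ξ, the multivariate p-value, and
the marginal p-values:

```
snp_id  xi        p_multivariate  p_trait_1  ...
snp1    28.51     0.0022          0.4158     ...
snp2    2.04      0.9487          0.7764     ...
```

The causal SNP (`snp1`) ranks 7th of 1861 by multivariate p-value
(0.0022) even though its best marginal p-value is only 0.0036 — the
joint test aggregates modest signals across the four traits. A single
e = 0.2 replicate rarely clears 10⁻⁶; the scripted power study
(`mvfisher experiment --kind power`) shows the multivariate test
rejecting at least as often as the marginal test in every
(scenario, ρ) cell.

`mvfisher oracle` prints the polynomial-vs-quadrature covariance
comparison; `mvfisher experiment --kind correlation|power|calibration|effectsize`
runs the simulation studies and writes tidy TSVs.

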