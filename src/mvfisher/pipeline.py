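"""End-to-end two-step multivariate GWAS.

Step 1: QC -> GRM -> PCs -> per-trait null REML fits -> per-SNP Wald
tests with plugged-in variance components.  Step 2: residual
correlations -> moment-matched gamma null -> per-SNP Fisher statistic
and multivariate p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mvio
from .fisher import GammaNull, gamma_moments, multivariate_p
from .genotype_sim import GenotypeData
from .grm import GRM, PrincipalComponents, compute_grm, compute_pcs, spectral_decompose
from .lmm import (NullModelFit, estimate_rho, fit_null, rotate_dosages,
                  snp_wald_many)

logger = logging.getLogger("mvfisher")

__all__ = ["AnalysisConfig", "AnalysisResult", "run_full_analysis", "analyze"]


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run."""

    genotype_prefix: str | None = None  # PLINK prefix
    genotype_tsv: str | None = None  # or TSV dosage matrix
    phenotype_path: str | None = None
    covariate_path: str | None = None
    n_pcs: int = 10
    maf_floor: float = 0.01
    hwe_p_floor: float = 1e-5
    snp_missingness_ceiling: float = 0.05
    significance_threshold: float = 1e-6
    autosomes_only: bool = True
    seed: int = 0
    output_prefix: str | None = None

    def validate(self) -> None:
        if (self.genotype_prefix is None) == (self.genotype_tsv is None):
            raise ValueError("provide exactly one genotype source")
        if not 0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in [0, 0.5)")
        if not 0 < self.significance_threshold < 1:
            raise ValueError("significance threshold must lie in (0, 1)")


@dataclass
class AnalysisResult:
    """Everything the two-step analysis produced."""

    marginal: pd.DataFrame  # snp_id, chr, pos, trait, beta, se, chi2, p
    combined: pd.DataFrame  # snp_id, chr, pos, xi, p_multivariate, p_trait_*
    rho_hat: np.ndarray
    gamma_null: GammaNull
    fits: list[NullModelFit] = field(repr=False)
    grm: GRM = field(repr=False)
    pcs: PrincipalComponents | None = field(repr=False, default=None)
    qc_report: mvio.QCReport | None = None
    n_subjects: int = 0


def _read_genotypes(config: AnalysisConfig) -> GenotypeData:
    if config.genotype_prefix is not None:
        return mvio.read_plink(config.genotype_prefix)
    return mvio.read_dosage_tsv(config.genotype_tsv)


def analyze(
    genotypes: GenotypeData,
    phenotypes: np.ndarray,
    trait_names=None,
    covariates: np.ndarray | None = None,
    n_pcs: int = 10,
    maf_floor: float = 0.01,
    hwe_p_floor: float = 1e-5,
    missing_ceiling: float = 0.05,
    run_qc: bool = True,
    grm: GRM | None = None,
) -> AnalysisResult:
    """In-memory two-step analysis on aligned genotype/phenotype arrays.

    ``phenotypes`` is an (N, R) array aligned to ``genotypes`` rows;
    ``covariates`` (optional) adds fixed effects beyond the intercept
    and the leading ``n_pcs`` genotype PCs.
    """
    y = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    if y.shape[0] != genotypes.n_subjects:
        raise ValueError("phenotype rows disagree with genotype subjects")
    r = y.shape[1]
    if trait_names is None:
        trait_names = [f"trait_{j + 1}" for j in range(r)]

    qc_report = None
    if run_qc:
        genotypes, qc_report = mvio.qc_filter(
            genotypes, maf_floor=maf_floor, hwe_p_floor=hwe_p_floor,
            missing_ceiling=missing_ceiling,
        )
        logger.info("QC: %s", qc_report)

    if grm is None:
        grm = compute_grm(genotypes, maf_floor=maf_floor)
    eigen = spectral_decompose(grm)
    pcs = compute_pcs(grm, n_pcs=n_pcs, eigen=eigen) if n_pcs else None

    n = genotypes.n_subjects
    x = np.ones((n, 1))
    if pcs is not None:
        x = np.column_stack([x, pcs.scores])
    if covariates is not None:
        x = np.column_stack([x, np.atleast_2d(np.asarray(covariates, float))])

    fits = [fit_null(y[:, j], x, eigen=eigen) for j in range(r)]
    for j, f in enumerate(fits):
        logger.info(
            "trait %s: sigma_g2=%.4f sigma_e2=%.4f lambda=%.4g",
            trait_names[j], f.sigma_g2, f.sigma_e2, f.lam,
        )

    dos = np.where(genotypes.dosages < 0, np.nan, genotypes.dosages.astype(float))
    col_mean = np.nanmean(dos, axis=0)
    idx = np.nonzero(np.isnan(dos))
    dos[idx] = np.take(col_mean, idx[1])

    marg_rows = []
    p_mat = np.empty((genotypes.n_snps, r))
    dos_rot = rotate_dosages(fits[0], dos)
    for j, f in enumerate(fits):
        beta, se, chi2, p = snp_wald_many(f, dos, rotated=dos_rot)
        p_mat[:, j] = p
        marg_rows.append(pd.DataFrame({
            "snp_id": genotypes.snp_ids,
            "chr": 1,
            "pos": np.arange(1, genotypes.n_snps + 1),
            "trait": trait_names[j],
            "beta": beta,
            "se": se,
            "chi2": chi2,
            "p": p,
        }))
    marginal = pd.concat(marg_rows, ignore_index=True)

    rho_hat = estimate_rho(fits)
    null = gamma_moments(rho_hat, n_subjects=n)
    logger.info("gamma null: k=%.5f theta=%.5f rho=%s", null.k, null.theta,
                np.round(rho_hat, 4).tolist())

    with np.errstate(divide="ignore"):
        logp = np.log(p_mat)
    ok = np.all(np.isfinite(logp), axis=1)
    xi = np.full(genotypes.n_snps, np.nan)
    xi[ok] = -2.0 * logp[ok].sum(axis=1)
    p_multi = np.full(genotypes.n_snps, np.nan)
    p_multi[ok] = multivariate_p(xi[ok], null)
    combined = pd.DataFrame({
        "snp_id": genotypes.snp_ids,
        "chr": 1,
        "pos": np.arange(1, genotypes.n_snps + 1),
        "xi": xi,
        "p_multivariate": p_multi,
    })
    for j in range(r):
        combined[f"p_{trait_names[j]}"] = p_mat[:, j]
    return AnalysisResult(
        marginal=marginal, combined=combined, rho_hat=rho_hat, gamma_null=null,
        fits=fits, grm=grm, pcs=pcs, qc_report=qc_report, n_subjects=n,
    )


def run_full_analysis(config: AnalysisConfig) -> AnalysisResult:
    """File-based analysis: read inputs, align subjects, run both steps,
    write marginal/combined TSVs and a parameter log."""
    config.validate()
    genotypes = _read_genotypes(config)
    if config.autosomes_only and genotypes.chromosomes is not None:
        autosome = np.isin(genotypes.chromosomes.astype(str),
                           [str(c) for c in range(1, 23)])
        if not autosome.all():
            logger.info("restricting to autosomes: dropping %d SNPs",
                        int((~autosome).sum()))
            genotypes = GenotypeData(
                dosages=genotypes.dosages[:, autosome],
                subject_ids=genotypes.subject_ids,
                snp_ids=genotypes.snp_ids[autosome],
                pedigree=genotypes.pedigree,
            )
    pheno = mvio.read_phenotypes(config.phenotype_path)
    trait_names = pheno.columns[2:].tolist()

    # align phenotype (and covariate) rows to genotype subjects by IID
    order = pd.Series(np.arange(len(pheno.index)), index=pheno["IID"])
    geno_ids = pd.Index(genotypes.subject_ids)
    matched = geno_ids[geno_ids.isin(order.index)]
    dropped = geno_ids.difference(matched)
    if len(dropped):
        logger.warning("excluding %d genotyped subjects without phenotypes: %s",
                       len(dropped), list(dropped[:5]))
    pheno = pheno.set_index("IID").loc[matched]
    complete = pheno[trait_names].notna().all(axis=1)
    if not complete.all():
        logger.warning(
            "dropping %d subjects with missing traits (imputation is out of "
            "scope here)", int((~complete).sum()))
        pheno = pheno[complete]
    keep_mask = np.isin(genotypes.subject_ids, pheno.index.to_numpy())
    genotypes = GenotypeData(
        dosages=genotypes.dosages[keep_mask],
        subject_ids=genotypes.subject_ids[keep_mask],
        snp_ids=genotypes.snp_ids,
        pedigree=None,
    )
    covar = None
    if config.covariate_path:
        cv = mvio.read_covariates(config.covariate_path).set_index("IID")
        cv = cv.loc[pheno.index]
        num = cv.drop(columns=["FID"], errors="ignore")
        covar = pd.get_dummies(num, drop_first=True).to_numpy(dtype=float)

    result = analyze(
        genotypes,
        pheno[trait_names].to_numpy(dtype=float),
        trait_names=trait_names,
        covariates=covar,
        n_pcs=config.n_pcs,
        maf_floor=config.maf_floor,
        hwe_p_floor=config.hwe_p_floor,
        missing_ceiling=config.snp_missingness_ceiling,
    )

    if config.output_prefix:
        prefix = Path(config.output_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        result.marginal.to_csv(f"{prefix}.marginal.tsv", sep="\t", index=False)
        combined = result.combined.copy()
        combined["significant"] = (
            combined["p_multivariate"] < config.significance_threshold
        )
        combined.to_csv(f"{prefix}.combined.tsv", sep="\t", index=False)
        _write_log(config, result, f"{prefix}.log")
    return result


def _write_log(config: AnalysisConfig, result: AnalysisResult, path) -> None:
    import mvfisher

    lines = [
        f"mvfisher {mvfisher.__version__}",
        f"config: {config}",
        f"subjects analyzed: {result.n_subjects}",
        f"QC: {result.qc_report}",
        f"gamma null: k={result.gamma_null.k!r} theta={result.gamma_null.theta!r}",
        f"rho_hat: {np.round(result.rho_hat, 6).tolist()}",
    ]
    for j, f in enumerate(result.fits):
        lines.append(
            f"trait {j + 1}: sigma_g2={f.sigma_g2:.6g} sigma_e2={f.sigma_e2:.6g} "
            f"lambda={f.lam:.6g} reml_loglik={f.reml_loglik:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
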