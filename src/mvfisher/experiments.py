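"""Scripted simulation studies.

Three study designs are provided, mirroring the evaluation a method
like this needs before real-data use:

* correlation-estimate accuracy — how well three estimators of the
  trait-trait residual correlation rho recover the truth (LMM
  residuals; LMM + 10 PC residuals; raw trait correlation);
* type-I error and power — marginal (trait 1) versus multivariate
  rejection rates over a (scenario, rho, e) grid with four traits;
* unequal effect sizes — multivariate power for effect-size vectors
  across traits on the related admixed design.

Desk-scale defaults (200 replicates, 2000 background SNPs) keep runs in
minutes; paper-scale settings (1000 replicates, 10000 SNPs) are plain
config values.  Within a cell, genotype cohorts are drawn from a small
pre-simulated pool whose GRM eigendecompositions are reused across
replicates; phenotypes are redrawn every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fisher import fisher_stat, gamma_moments, multivariate_p
from .genotype_sim import SCENARIOS, simulate_cohort
from .grm import compute_grm, compute_pcs, spectral_decompose
from .lmm import estimate_rho, fit_null, naive_rho, snp_wald_many
from .phenotype_sim import PhenoSimConfig, simulate_phenotypes

__all__ = [
    "ExperimentGrid",
    "run_correlation_accuracy",
    "run_power_type1",
    "run_null_calibration",
    "run_effectsize_grid",
    "summarize_rejection",
    "plot_boxplots",
]


@dataclass(frozen=True)
class ExperimentGrid:
    """One simulation-study configuration.

    ``cohort_pool`` genotype cohorts are pre-simulated per scenario and
    cycled across replicates.
    """

    scenarios: tuple = SCENARIOS
    rho_values: tuple = (0.0, 0.3, 0.6, 0.9)
    e_values: tuple = (0.0, 0.5, 1.0)
    replicates: int = 200
    n_snps: int = 2000
    seed: int = 0
    alpha: float = 0.05
    n_pcs: int = 10
    cohort_pool: int = 10
    causal_snp_index: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")


@dataclass
class _Cohort:
    genotypes: object
    eigen: object
    x_intercept: np.ndarray
    x_pcs: np.ndarray


def _build_pool(scenario, grid: ExperimentGrid, seed_seq) -> list[_Cohort]:
    pool = []
    for child in seed_seq.spawn(grid.cohort_pool):
        rng = np.random.default_rng(child)
        coh = simulate_cohort(scenario, n_snps=grid.n_snps, seed=rng)
        grm = compute_grm(coh)
        eigen = spectral_decompose(grm)
        pcs = compute_pcs(grm, n_pcs=grid.n_pcs, eigen=eigen)
        n = coh.n_subjects
        ones = np.ones((n, 1))
        pool.append(_Cohort(
            genotypes=coh,
            eigen=eigen,
            x_intercept=ones,
            x_pcs=np.column_stack([ones, pcs.scores]),
        ))
    return pool


def run_correlation_accuracy(grid: ExperimentGrid) -> pd.DataFrame:
    """Bivariate rho-recovery study: tidy rows per
    (scenario, rho, e, replicate, method) with rho_hat and bias."""
    root = np.random.SeedSequence(grid.seed)
    rows = []
    for scenario, sc_seq in zip(grid.scenarios, root.spawn(len(grid.scenarios))):
        geno_seq, pheno_seq = sc_seq.spawn(2)
        pool = _build_pool(scenario, grid, geno_seq)
        rng = np.random.default_rng(pheno_seq)
        for rho in grid.rho_values:
            for e in grid.e_values:
                cfg = PhenoSimConfig(
                    n_traits=2, effect_sizes=e, rho=rho,
                    causal_snp_index=grid.causal_snp_index,
                )
                for rep in range(grid.replicates):
                    coh = pool[rep % len(pool)]
                    ph = simulate_phenotypes(coh.genotypes, cfg, seed=rng)
                    fits1 = [fit_null(ph.values[:, j], coh.x_intercept,
                                      eigen=coh.eigen) for j in range(2)]
                    fits2 = [fit_null(ph.values[:, j], coh.x_pcs,
                                      eigen=coh.eigen) for j in range(2)]
                    est = {
                        "lmm": estimate_rho(fits1)[0, 1],
                        "lmm_pcs": estimate_rho(fits2)[0, 1],
                        "naive": naive_rho(ph)[0, 1],
                    }
                    for method, rho_hat in est.items():
                        rows.append((scenario, rho, e, rep, method,
                                     rho_hat, rho_hat - rho))
    return pd.DataFrame(
        rows, columns=["scenario", "rho", "e", "replicate", "method",
                       "rho_hat", "bias"],
    )


def _one_combined_test(coh: _Cohort, values: np.ndarray, causal_index: int):
    """Fit the null per trait, test the causal SNP, combine."""
    r = values.shape[1]
    fits = [fit_null(values[:, j], coh.x_pcs, eigen=coh.eigen) for j in range(r)]
    g = coh.genotypes.dosages[:, causal_index].astype(float)
    p_marg = np.empty(r)
    for j, f in enumerate(fits):
        _, _, _, p = snp_wald_many(f, g)
        p_marg[j] = p[0]
    rho_hat = estimate_rho(fits)
    null = gamma_moments(rho_hat, n_subjects=values.shape[0])
    xi = fisher_stat(p=p_marg)
    return p_marg, multivariate_p(xi, null)


def run_power_type1(grid: ExperimentGrid, n_traits: int = 4) -> pd.DataFrame:
    """Replicate-level causal-SNP p-values for the trait-1 marginal and
    the multivariate test over the (scenario, rho, e) grid."""
    root = np.random.SeedSequence(grid.seed)
    rows = []
    for scenario, sc_seq in zip(grid.scenarios, root.spawn(len(grid.scenarios))):
        geno_seq, pheno_seq = sc_seq.spawn(2)
        pool = _build_pool(scenario, grid, geno_seq)
        rng = np.random.default_rng(pheno_seq)
        for rho in grid.rho_values:
            for e in grid.e_values:
                cfg = PhenoSimConfig(
                    n_traits=n_traits, effect_sizes=e, rho=rho,
                    causal_snp_index=grid.causal_snp_index,
                )
                for rep in range(grid.replicates):
                    coh = pool[rep % len(pool)]
                    ph = simulate_phenotypes(coh.genotypes, cfg, seed=rng)
                    p_marg, p_multi = _one_combined_test(
                        coh, ph.values, grid.causal_snp_index)
                    rows.append((scenario, rho, e, rep, p_marg[0], p_multi))
    return pd.DataFrame(
        rows, columns=["scenario", "rho", "e", "replicate",
                       "p_marginal", "p_multivariate"],
    )


def run_null_calibration(grid: ExperimentGrid, n_traits: int = 4) -> pd.DataFrame:
    """Genome-wide null run: e = 0 traits tested against every SNP.

    One cohort per scenario; returns per-SNP marginal (trait 1) and
    multivariate p-values for each rho, for uniformity checks.
    """
    root = np.random.SeedSequence(grid.seed)
    frames = []
    for scenario, sc_seq in zip(grid.scenarios, root.spawn(len(grid.scenarios))):
        geno_seq, pheno_seq = sc_seq.spawn(2)
        rng_g = np.random.default_rng(geno_seq)
        coh_data = simulate_cohort(scenario, n_snps=grid.n_snps, seed=rng_g)
        grm = compute_grm(coh_data)
        eigen = spectral_decompose(grm)
        pcs = compute_pcs(grm, n_pcs=grid.n_pcs, eigen=eigen)
        x = np.column_stack([np.ones((coh_data.n_subjects, 1)), pcs.scores])
        rng = np.random.default_rng(pheno_seq)
        dos = coh_data.dosages.astype(float)
        dos_rot = eigen.vectors.T @ dos  # shared across rho values and traits
        for rho in grid.rho_values:
            cfg = PhenoSimConfig(n_traits=n_traits, effect_sizes=0.0, rho=rho)
            ph = simulate_phenotypes(coh_data, cfg, seed=rng)
            fits = [fit_null(ph.values[:, j], x, eigen=eigen)
                    for j in range(n_traits)]
            p_mat = np.column_stack(
                [snp_wald_many(f, dos, rotated=dos_rot)[3] for f in fits])
            rho_hat = estimate_rho(fits)
            null = gamma_moments(rho_hat, n_subjects=coh_data.n_subjects)
            xi = -2.0 * np.log(p_mat).sum(axis=1)
            frames.append(pd.DataFrame({
                "scenario": scenario,
                "rho": rho,
                "snp_id": coh_data.snp_ids,
                "p_marginal": p_mat[:, 0],
                "p_multivariate": multivariate_p(xi, null),
            }))
    return pd.concat(frames, ignore_index=True)


DEFAULT_EFFECT_VECTORS = {
    "small": (0.1, 0.1, 0.1, 0.1),
    "increasing": (0.05, 0.1, 0.15, 0.2),
    "medium": (0.15, 0.15, 0.15, 0.15),
}


def run_effectsize_grid(
    grid: ExperimentGrid,
    effect_vectors: dict[str, tuple] | None = None,
    rho_values: tuple = (0.1, 0.5),
    scenario: str = "admixed-related",
) -> pd.DataFrame:
    """Unequal-effect-size power study on the related admixed design."""
    effect_vectors = effect_vectors or DEFAULT_EFFECT_VECTORS
    for label, e in effect_vectors.items():
        if not np.any(np.asarray(e)):
            raise ValueError(
                f"effect vector {label!r} is all zero; the no-effect case "
                "belongs to the type-I study, not the power grid"
            )
    root = np.random.SeedSequence(grid.seed)
    geno_seq, pheno_seq = root.spawn(2)
    pool = _build_pool(scenario, grid, geno_seq)
    rng = np.random.default_rng(pheno_seq)
    rows = []
    for rho in rho_values:
        for label, evec in effect_vectors.items():
            cfg = PhenoSimConfig(
                n_traits=len(evec), effect_sizes=np.asarray(evec, float),
                rho=rho, causal_snp_index=grid.causal_snp_index,
            )
            for rep in range(grid.replicates):
                coh = pool[rep % len(pool)]
                ph = simulate_phenotypes(coh.genotypes, cfg, seed=rng)
                p_marg, p_multi = _one_combined_test(
                    coh, ph.values, grid.causal_snp_index)
                rows.append((scenario, rho, label, rep, p_marg[0], p_multi))
    return pd.DataFrame(
        rows, columns=["scenario", "rho", "effects", "replicate",
                       "p_marginal", "p_multivariate"],
    )


def summarize_rejection(results: pd.DataFrame, alpha: float = 0.05,
                        by=("scenario", "rho", "e")) -> pd.DataFrame:
    """Rejection rates of both tests per grid cell."""
    by = [c for c in by if c in results.columns]
    out = results.groupby(by, as_index=False).agg(
        n=("replicate", "size"),
        reject_marginal=("p_marginal", lambda p: float(np.mean(p < alpha))),
        reject_multivariate=("p_multivariate",
                             lambda p: float(np.mean(p < alpha))),
    )
    return out


def plot_boxplots(results: pd.DataFrame, value: str, by: str, ax=None,
                  log10: bool = False):
    """Boxplot of one result column grouped by a grid column."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    groups = sorted(results[by].unique())
    data = [results.loc[results[by] == g, value].dropna() for g in groups]
    if log10:
        data = [-np.log10(d) for d in data]
    ax.boxplot(data, tick_labels=[str(g) for g in groups])
    ax.set_xlabel(by)
    ax.set_ylabel(f"-log10({value})" if log10 else value)
    return ax
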