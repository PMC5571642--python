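"""Spectral REML, plug-in Wald tests and residual correlations."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from mvfisher.genotype_sim import GenotypeData
from mvfisher.grm import GRM, spectral_decompose
from mvfisher.lmm import (
    estimate_rho,
    fit_null,
    naive_rho,
    snp_wald,
    snp_wald_many,
)
from mvfisher.phenotype_sim import (
    PhenoSimConfig,
    PhenotypeData,
    simulate_phenotypes,
    simulate_polygenic_traits,
)


def _grid_loglik(fit, n_grid=33):
    from mvfisher.lmm import LAMBDA_BOUNDS, _reml_loglik

    grid = np.logspace(*np.log10(LAMBDA_BOUNDS), n_grid)
    return _reml_loglik(grid, np.clip(fit.eigen.values, 0, None),
                        fit.x_rot, fit.y_rot)


def _gls_oracle(y, x, g, k, sigma_g2, sigma_e2):
    """Direct generalized least squares with explicit V, no rotation."""
    v = sigma_g2 * k + sigma_e2 * np.eye(len(y))
    xt = np.column_stack([x, g])
    vi_x = np.linalg.solve(v, xt)
    info = xt.T @ vi_x
    beta = np.linalg.solve(info, vi_x.T @ y)
    cov = np.linalg.inv(info)
    return beta[-1], np.sqrt(cov[-1, -1])


class TestFitNull:
    def test_variance_components_recovered(self, related_eigen):
        rng = np.random.default_rng(21)
        x = np.ones((1000, 1))
        est = []
        for _ in range(40):
            y = simulate_polygenic_traits(
                related_eigen.values, related_eigen.vectors, 0.5, 0.5, seed=rng
            )[:, 0]
            f = fit_null(y, x, eigen=related_eigen)
            est.append((f.sigma_g2, f.sigma_e2))
        mean = np.mean(est, axis=0)
        assert mean == pytest.approx([0.5, 0.5], abs=0.1)

    def test_no_heritability_shrinks_lambda(self, related_eigen):
        rng = np.random.default_rng(22)
        y = rng.standard_normal(1000)  # independent of the GRM
        f = fit_null(y, np.ones((1000, 1)), eigen=related_eigen)
        assert f.sigma_g2 < 0.1 * f.sigma_e2
        total = f.sigma_g2 + f.sigma_e2
        assert total == pytest.approx(np.var(y), rel=0.1)

    def test_refined_optimum_beats_grid(self, related_eigen, rng):
        y = simulate_polygenic_traits(
            related_eigen.values, related_eigen.vectors, 0.7, 0.3, seed=rng
        )[:, 0]
        f = fit_null(y, np.ones((1000, 1)), eigen=related_eigen)
        assert np.all(f.reml_loglik >= _grid_loglik(f) - 1e-8)

    def test_residual_decomposition_identity(self, related_eigen, rng):
        n = 1000
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = simulate_polygenic_traits(
            related_eigen.values, related_eigen.vectors, 0.5, 0.5, seed=rng
        )[:, 0]
        f = fit_null(y, x, eigen=related_eigen)
        np.testing.assert_allclose(
            f.residuals, y - x @ f.fixed_effects - f.blup, atol=1e-10
        )
        assert f.sigma_g2 >= 0 and f.sigma_e2 > 0

    def test_perfect_fit_floors_residual_variance(self, related_eigen, rng):
        n = 1000
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = x @ np.array([2.0, -1.0])
        f = fit_null(y, x, eigen=related_eigen)
        assert np.abs(f.residuals).max() < 1e-6
        assert f.sigma_e2 <= 1e-10

    def test_rank_deficient_covariates_rejected(self, related_eigen):
        x = np.ones((1000, 2))
        with pytest.raises(ValueError):
            fit_null(np.zeros(1000), x, eigen=related_eigen)

    def test_non_finite_phenotype_rejected(self, related_eigen):
        y = np.zeros(1000)
        y[0] = np.nan
        with pytest.raises(ValueError):
            fit_null(y, np.ones((1000, 1)), eigen=related_eigen)


class TestSnpWald:
    def test_matches_direct_gls(self, related_cohort, related_grm,
                                related_eigen, rng):
        n = 1000
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = simulate_polygenic_traits(
            related_eigen.values, related_eigen.vectors, 0.4, 0.6, seed=rng
        )[:, 0]
        f = fit_null(y, x, eigen=related_eigen)
        for j in (0, 7, 101):
            g = related_cohort.dosages[:, j].astype(float)
            got = snp_wald(f, g, snp_id=f"snp{j}")
            beta, se = _gls_oracle(y, x, g, related_grm.matrix,
                                   f.sigma_g2, f.sigma_e2)
            assert got.beta_hat == pytest.approx(beta, abs=1e-8)
            assert got.se == pytest.approx(se, abs=1e-8)
            assert got.wald_chi2 == pytest.approx((beta / se) ** 2, rel=1e-6)
            assert got.p_value == pytest.approx(
                stats.chi2.sf((beta / se) ** 2, 1), rel=1e-9
            )

    def test_reduces_to_ols_when_lambda_vanishes(self, related_cohort,
                                                 related_eigen, rng):
        n = 1000
        x = np.ones((n, 1))
        y = rng.standard_normal(n)
        f = fit_null(y, x, eigen=related_eigen, lambda_bounds=(1e-12, 1e-11))
        g = related_cohort.dosages[:, 3].astype(float)
        got = snp_wald(f, g)
        # OLS on intercept-residualized data, residual variance from the
        # null model (n - p denominator), computed directly
        yc, gc = y - y.mean(), g - g.mean()
        beta = (gc @ yc) / (gc @ gc)
        se = np.sqrt((yc @ yc) / (n - 1) / (gc @ gc))
        assert got.beta_hat == pytest.approx(beta, abs=1e-8)
        assert got.se == pytest.approx(se, abs=1e-8)

    def test_monomorphic_snp_rejected(self, related_eigen, rng):
        f = fit_null(rng.standard_normal(1000), np.ones((1000, 1)),
                     eigen=related_eigen)
        with pytest.raises(ValueError):
            snp_wald(f, np.ones(1000))

    def test_null_p_values_uniform(self, related_cohort, related_eigen, rng):
        y = rng.standard_normal(1000)
        f = fit_null(y, np.ones((1000, 1)), eigen=related_eigen)
        p = snp_wald_many(f, related_cohort.dosages)[3]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_order_invariance(self, related_cohort, related_eigen, rng):
        y = rng.standard_normal(1000)
        f = fit_null(y, np.ones((1000, 1)), eigen=related_eigen)
        d = related_cohort.dosages[:, :50]
        perm = rng.permutation(50)
        p_full = snp_wald_many(f, d)[3]
        p_perm = snp_wald_many(f, d[:, perm])[3]
        np.testing.assert_allclose(p_perm, p_full[perm], rtol=1e-12)

    def test_plugin_agrees_with_per_snp_refit(self, related_cohort,
                                              related_eigen, rng):
        """Refitting variance components with the SNP included changes
        the rejection decision for almost no null SNPs."""
        n, n_snps, alpha = 1000, 500, 0.05
        x = np.ones((n, 1))
        y = simulate_polygenic_traits(
            related_eigen.values, related_eigen.vectors, 0.5, 0.5, seed=rng
        )[:, 0]
        f0 = fit_null(y, x, eigen=related_eigen)
        p_plug = snp_wald_many(f0, related_cohort.dosages[:, :n_snps])[3]
        agree = 0
        for j in range(n_snps):
            g = related_cohort.dosages[:, j].astype(float)
            fj = fit_null(y, np.column_stack([x, g]), eigen=related_eigen)
            fx = replace(f0, sigma_g2=fj.sigma_g2, sigma_e2=fj.sigma_e2,
                         lam=fj.lam)
            p_exact = snp_wald(fx, g).p_value
            agree += (p_exact < alpha) == (p_plug[j] < alpha)
        assert agree / n_snps >= 0.95


class TestRho:
    def test_single_trait_degenerate(self, related_eigen, rng):
        f = fit_null(rng.standard_normal(1000), np.ones((1000, 1)),
                     eigen=related_eigen)
        np.testing.assert_array_equal(estimate_rho([f]), [[1.0]])

    def test_recovers_truth_for_independent_subjects(self, independent_cohort):
        cfg = PhenoSimConfig(n_traits=2, effect_sizes=0.0, rho=0.5)
        ph = simulate_phenotypes(independent_cohort, cfg, seed=31)
        from mvfisher.grm import compute_grm

        eigen = spectral_decompose(compute_grm(independent_cohort))
        fits = [fit_null(ph.values[:, j], np.ones((1000, 1)), eigen=eigen)
                for j in range(2)]
        assert estimate_rho(fits)[0, 1] == pytest.approx(0.5, abs=0.06)

    def test_naive_matches_adjusted_without_genetic_effect(
            self, independent_cohort):
        from mvfisher.grm import compute_grm

        eigen = spectral_decompose(compute_grm(independent_cohort))
        cfg = PhenoSimConfig(n_traits=2, effect_sizes=0.0, rho=0.3)
        diffs = []
        for seed in range(10):
            ph = simulate_phenotypes(independent_cohort, cfg, seed=seed)
            fits = [fit_null(ph.values[:, j], np.ones((1000, 1)), eigen=eigen)
                    for j in range(2)]
            diffs.append(abs(estimate_rho(fits)[0, 1] - naive_rho(ph)[0, 1]))
        assert np.mean(diffs) < 0.02

    def test_naive_overestimates_on_related_data(self, related_cohort,
                                                 related_eigen):
        """Large shared causal effects inflate the raw trait correlation;
        mixed-model residuals absorb part of the inflation."""
        cfg = PhenoSimConfig(n_traits=2, effect_sizes=1.0, rho=0.0)
        naive, adjusted = [], []
        for seed in range(30):
            ph = simulate_phenotypes(related_cohort, cfg, seed=seed)
            fits = [fit_null(ph.values[:, j], np.ones((1000, 1)),
                             eigen=related_eigen) for j in range(2)]
            adjusted.append(estimate_rho(fits)[0, 1])
            naive.append(naive_rho(ph)[0, 1])
        assert np.mean(naive) > 0
        assert np.mean(adjusted) < np.mean(naive)

    def test_zero_variance_trait_rejected(self):
        ph = PhenotypeData(
            values=np.column_stack([np.ones(10), np.arange(10.0)]),
            subject_ids=np.arange(10).astype(str),
            trait_names=np.array(["a", "b"]),
        )
        with pytest.raises(ValueError):
            naive_rho(ph)

    def test_mismatched_fits_rejected(self, related_eigen, rng):
        f = fit_null(rng.standard_normal(1000), np.ones((1000, 1)),
                     eigen=related_eigen)
        small = GRM(matrix=np.eye(10), n_snps_used=1,
                    subject_ids=np.arange(10).astype(str))
        g = fit_null(rng.standard_normal(10), np.ones((10, 1)),
                     eigen=spectral_decompose(small))
        with pytest.raises(ValueError):
            estimate_rho([f, g])
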