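"""Correlated quantitative phenotypes with an additive causal SNP.

Each subject's R-vector of traits is multivariate normal,

    y_i ~ MVN(mu(g_i), Sigma),   mu_r(g) = (g - 1) * e_r,

so genotype AA (dosage 0) shifts trait r by -e_r, AB (1) by 0 and BB
(2) by +e_r, and Sigma is exchangeable with unit diagonal and common
off-diagonal correlation rho.  Subjects are independent given their
genotypes; relatedness enters the traits only through shared causal
genotypes within a family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_sim import GenotypeData

__all__ = [
    "PhenoSimConfig",
    "PhenotypeData",
    "genetic_mean",
    "exchangeable_cov",
    "simulate_phenotypes",
    "simulate_polygenic_traits",
]


def exchangeable_cov(n_traits: int, rho: float) -> np.ndarray:
    """Unit-diagonal exchangeable covariance; positive definite iff
    -1/(R-1) < rho < 1."""
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    if n_traits > 1 and not (-1.0 / (n_traits - 1) < rho < 1.0):
        raise ValueError(
            f"rho={rho} gives a non-positive-definite {n_traits}x{n_traits} "
            "exchangeable covariance"
        )
    sigma = np.full((n_traits, n_traits), float(rho))
    np.fill_diagonal(sigma, 1.0)
    return sigma


@dataclass(frozen=True)
class PhenoSimConfig:
    """One phenotype-simulation setting.

    ``effect_sizes`` may be a scalar (shared by all traits) or a length-R
    vector; ``sigma`` overrides the exchangeable structure when a
    non-exchangeable covariance is wanted.
    """

    n_traits: int
    effect_sizes: np.ndarray | float
    rho: float = 0.0
    sigma: np.ndarray | None = field(default=None, repr=False)
    causal_snp_index: int = 0

    def effects(self) -> np.ndarray:
        e = np.broadcast_to(
            np.asarray(self.effect_sizes, dtype=float), (self.n_traits,)
        ).copy()
        if not np.all(np.isfinite(e)):
            raise ValueError("effect sizes must be finite")
        return e

    def covariance(self) -> np.ndarray:
        if self.sigma is not None:
            sig = np.asarray(self.sigma, dtype=float)
            if sig.shape != (self.n_traits, self.n_traits):
                raise ValueError("sigma shape inconsistent with n_traits")
            if np.any(np.linalg.eigvalsh(sig) <= 0):
                raise ValueError("sigma must be positive definite")
            return sig
        return exchangeable_cov(self.n_traits, self.rho)


@dataclass
class PhenotypeData:
    """N x R matrix of quantitative traits with subject alignment."""

    values: np.ndarray
    subject_ids: np.ndarray
    trait_names: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.trait_names)):
            raise ValueError("phenotype matrix shape inconsistent with ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotypes must be finite")

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]


def genetic_mean(dosage, effect_size):
    """Additive genetic mean: -e, 0, +e for dosages 0, 1, 2."""
    d = np.asarray(dosage)
    if not np.isin(d, (0, 1, 2)).all():
        raise ValueError("dosage must be 0, 1 or 2")
    out = (d.astype(float) - 1.0) * effect_size
    return out if out.ndim else float(out)


def simulate_phenotypes(
    genotypes: GenotypeData, config: PhenoSimConfig, seed=None
) -> PhenotypeData:
    """Draw MVN traits around the causal-SNP additive means."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not 0 <= config.causal_snp_index < genotypes.n_snps:
        raise ValueError("causal SNP index out of range")
    g = genotypes.dosages[:, config.causal_snp_index]
    e = config.effects()
    mu = genetic_mean(g, 1.0)[:, None] * e[None, :]
    chol = np.linalg.cholesky(config.covariance())
    noise = rng.standard_normal((genotypes.n_subjects, config.n_traits)) @ chol.T
    values = mu + noise
    names = np.array([f"trait_{r + 1}" for r in range(config.n_traits)])
    return PhenotypeData(
        values=values, subject_ids=genotypes.subject_ids.copy(), trait_names=names
    )


def simulate_polygenic_traits(
    eigenvalues: np.ndarray,
    eigenvectors: np.ndarray,
    sigma_g2: float,
    sigma_e2: float,
    n_traits: int = 1,
    seed=None,
) -> np.ndarray:
    """Traits with a polygenic component: y = z + eps, z ~ N(0, sigma_g2 K).

    Used for variance-component recovery checks; the causal-SNP model
    above has no polygenic term.  ``eigenvalues``/``eigenvectors`` are
    the spectral decomposition of the GRM (small negative eigenvalues
    are clipped at zero).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    n = lam.shape[0]
    z = eigenvectors @ (
        np.sqrt(sigma_g2 * lam)[:, None] * rng.standard_normal((n, n_traits))
    )
    eps = np.sqrt(sigma_e2) * rng.standard_normal((n, n_traits))
    return z + eps
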