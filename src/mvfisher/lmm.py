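"""Single-GRM linear mixed models for marginal GWAS.

Per trait the null model is

    y = X b + z + eps,   z ~ N(0, sigma_g^2 K),   eps ~ N(0, sigma^2 I),

with X the fixed-effect design (intercept, optional PCs/covariates) and
K the genetic relationship matrix.  REML estimation reduces to a 1-D
search over the variance ratio lambda = sigma_g^2 / sigma^2: after one
eigendecomposition K = U L U', every likelihood evaluation is O(N p^2)
in the rotated basis, and sigma^2 is profiled out in closed form
(EMMA-style spectral REML).

Each SNP is then tested with a Wald statistic whose variance uses the
null-model variance components plugged in: generalized least squares of
[X, g] under V-hat = sigma_g^2 K + sigma^2 I, O(N) per SNP after the
one-time rotation.  Conditional residuals eps-hat = y - X b-hat - z-hat
(BLUP subtracted) estimate the trait-trait residual correlation rho
that calibrates the combined test's gamma null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .grm import GRM, GRMEigen, spectral_decompose
from .phenotype_sim import PhenotypeData

__all__ = [
    "NullModelFit",
    "MarginalAssoc",
    "fit_null",
    "snp_wald",
    "snp_wald_many",
    "rotate_dosages",
    "estimate_rho",
    "naive_rho",
]

LAMBDA_BOUNDS = (1e-6, 1e6)
N_GRID = 33  # log-spaced REML grid points bracketing the refinement


@dataclass
class NullModelFit:
    """REML fit of the no-SNP model for one trait.

    Holds the variance components, fixed effects, BLUP and conditional
    residuals, plus rotated data reused by every SNP test.
    """

    sigma_g2: float
    sigma_e2: float
    lam: float
    fixed_effects: np.ndarray
    blup: np.ndarray
    residuals: np.ndarray
    reml_loglik: float
    eigen: GRMEigen = field(repr=False)
    y_rot: np.ndarray = field(repr=False)
    x_rot: np.ndarray = field(repr=False)

    @property
    def n_subjects(self) -> int:
        return self.y_rot.shape[0]


@dataclass(frozen=True)
class MarginalAssoc:
    """Per-SNP, per-trait Wald test result (1-df chi-square)."""

    snp_id: str
    trait_index: int
    beta_hat: float
    se: float
    wald_chi2: float
    p_value: float


def _reml_parts(lam, vals, x_rot, y_rot):
    """Profiled REML pieces at a given lambda (vectorized over a
    lambda grid when ``lam`` is an array)."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    d = lam[:, None] * vals[None, :] + 1.0  # (L, N)
    w = 1.0 / d
    # XtWX: (L, p, p); XtWy: (L, p)
    xw = x_rot[None, :, :] * w[:, :, None]
    xtwx = np.einsum("lnp,nq->lpq", xw, x_rot)
    xtwy = np.einsum("lnp,n->lp", xw, y_rot)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    resid = y_rot[None, :] - np.einsum("np,lp->ln", x_rot, beta)
    rss = np.einsum("ln,ln->l", resid**2, w)
    return d, xtwx, beta, rss


def _reml_loglik(lam, vals, x_rot, y_rot):
    n, p = x_rot.shape
    d, xtwx, _, rss = _reml_parts(lam, vals, x_rot, y_rot)
    nf = n - p
    sigma2 = np.maximum(rss / nf, 1e-300)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    ll = -0.5 * (
        nf * (np.log(2.0 * np.pi * sigma2) + 1.0)
        + np.sum(np.log(d), axis=1)
        + logdet_xtwx
    )
    return ll


def fit_null(
    y,
    covariates,
    grm: GRM | None = None,
    eigen: GRMEigen | None = None,
    lambda_bounds=LAMBDA_BOUNDS,
    n_grid: int = N_GRID,
) -> NullModelFit:
    """REML fit of y = Xb + z + eps over lambda = sigma_g^2 / sigma^2.

    A log-spaced grid locates the likelihood's basin; bounded scalar
    refinement then polishes the optimum (ties resolved toward the
    smaller lambda).  Either a GRM or its precomputed decomposition must
    be supplied; pass the same :class:`GRMEigen` for every trait to
    amortize the eigendecomposition.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("covariates and y disagree on N")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    if eigen is None:
        if grm is None:
            raise ValueError("provide a GRM or its eigendecomposition")
        eigen = spectral_decompose(grm)
    vals = np.clip(eigen.values, 0.0, None)  # guard tiny negative eigenvalues
    u = eigen.vectors
    y_rot = u.T @ y
    x_rot = u.T @ x

    lo, hi = lambda_bounds
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    ll = _reml_loglik(grid, vals, x_rot, y_rot)
    best = int(np.argmax(ll))
    # refine within the bracketing grid interval (log scale)
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_reml_loglik(np.exp(t), vals, x_rot, y_rot)[0],
        bounds=(np.log(a), np.log(b)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    cand = np.exp(res.x)
    cand_ll = -res.fun
    if cand_ll >= ll[best]:
        lam, lam_ll = float(cand), float(cand_ll)
    else:
        lam, lam_ll = float(grid[best]), float(ll[best])
    if abs(cand_ll - ll[best]) <= 1e-10 * max(1.0, abs(ll[best])):
        lam = float(min(cand, grid[best]))  # tie toward smaller lambda

    n, p = x_rot.shape
    d, xtwx, beta, rss = _reml_parts(lam, vals, x_rot, y_rot)
    d, beta = d[0], beta[0]
    var_y = float(np.var(y)) or 1.0
    sigma_e2 = max(float(rss[0]) / (n - p), 1e-12 * var_y)
    sigma_g2 = lam * sigma_e2
    if lam <= lambda_bounds[0] * (1 + 1e-9):
        sigma_g2 = lam * sigma_e2  # effectively zero heritability; keep >= 0

    resid_rot = y_rot - x_rot @ beta  # marginal residuals, rotated
    eps_rot = resid_rot / d  # conditional residuals: (I - lam*L/(lam*L+1)) r
    blup_rot = resid_rot - eps_rot
    return NullModelFit(
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        lam=float(lam),
        fixed_effects=beta,
        blup=u @ blup_rot,
        residuals=u @ eps_rot,
        reml_loglik=float(lam_ll),
        eigen=eigen,
        y_rot=y_rot,
        x_rot=x_rot,
    )


def _gls_weights(fit: NullModelFit) -> np.ndarray:
    vals = np.clip(fit.eigen.values, 0.0, None)
    return 1.0 / (fit.sigma_g2 * vals + fit.sigma_e2)


def rotate_dosages(fit: NullModelFit, dosages) -> np.ndarray:
    """Pre-rotate an (N, S) dosage block into the GRM eigenbasis so the
    same block can be tested against several trait fits sharing one
    decomposition."""
    g = np.asarray(dosages, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    return fit.eigen.vectors.T @ g


def snp_wald_many(fit: NullModelFit, dosages, rotated=None):
    """Vectorized plug-in Wald tests for an (N, S) dosage block.

    Returns arrays (beta, se, chi2, p).  Monomorphic SNPs yield NaN
    rows rather than raising, so callers can batch genome-wide scans;
    the scalar :func:`snp_wald` wrapper raises on degenerate input.
    ``rotated`` (from :func:`rotate_dosages`) skips the per-call basis
    rotation.
    """
    g = np.asarray(dosages, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    w = _gls_weights(fit)
    g_rot = rotate_dosages(fit, g) if rotated is None else rotated  # (N, S)
    x, y = fit.x_rot, fit.y_rot
    xw = x * w[:, None]
    a = x.T @ xw  # p x p
    b = x.T @ (w * y)
    a_inv_b = np.linalg.solve(a, b)
    xg = xw.T @ g_rot  # (p, S)
    a_inv_xg = np.linalg.solve(a, xg)
    gy = g_rot.T @ (w * y) - xg.T @ a_inv_b  # projected g'Wy
    gg = np.einsum("ns,ns->s", g_rot * w[:, None], g_rot) - np.einsum(
        "ps,ps->s", xg, a_inv_xg
    )
    poly = np.nanvar(g, axis=0) <= 0
    gg_safe = np.where(gg > 0, gg, np.nan)
    beta = gy / gg_safe
    se = np.sqrt(1.0 / gg_safe)
    beta = np.where(poly, np.nan, beta)
    se = np.where(poly, np.nan, se)
    chi2 = (beta / se) ** 2
    p = stats.chi2.sf(chi2, df=1)
    return beta, se, chi2, p


def snp_wald(fit: NullModelFit, dosage, snp_id: str = "snp", trait_index: int = 0
             ) -> MarginalAssoc:
    """Plug-in Wald test of one SNP against one fitted trait."""
    g = np.asarray(dosage, dtype=float).ravel()
    if g.shape[0] != fit.n_subjects:
        raise ValueError("dosage length disagrees with the fitted model")
    if np.var(g) <= 0:
        raise ValueError(f"SNP {snp_id!r} is monomorphic in this sample")
    beta, se, chi2, p = snp_wald_many(fit, g)
    return MarginalAssoc(
        snp_id=snp_id,
        trait_index=trait_index,
        beta_hat=float(beta[0]),
        se=float(se[0]),
        wald_chi2=float(chi2[0]),
        p_value=float(p[0]),
    )


def _corr(columns: np.ndarray) -> np.ndarray:
    sd = columns.std(axis=0)
    if np.any(sd <= 0):
        raise ValueError("zero-variance vector; correlation undefined")
    if columns.shape[1] == 1:
        return np.ones((1, 1))
    c = np.corrcoef(columns, rowvar=False)
    return 0.5 * (c + c.T)


def estimate_rho(fits: list[NullModelFit]) -> np.ndarray:
    """Pearson correlation matrix of the traits' conditional residuals."""
    n = {f.n_subjects for f in fits}
    if len(n) != 1:
        raise ValueError("fits disagree on subject count/order")
    return _corr(np.column_stack([f.residuals for f in fits]))


def naive_rho(phenotypes: PhenotypeData) -> np.ndarray:
    """Raw trait correlation — the unadjusted comparison baseline, which
    overestimates rho when related subjects share causal genotypes."""
    return _corr(phenotypes.values)
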