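"""Fisher combination of dependent marginal p-values with a gamma null.

The pleiotropy statistic for SNP *s* over *R* traits is

    xi_s = sum_r -2 log(p_rs),

the classic Fisher combination.  With independent traits xi_s is
chi-square with 2R degrees of freedom, but marginal GWAS p-values from
correlated traits are dependent, so xi_s is instead approximated by a
gamma distribution whose shape ``k`` and scale ``theta`` are fixed by
moment matching:

    k * theta   = 2R
    k * theta^2 = 4R + sum_{r != r'} cov(-2 log p_r, -2 log p_r').

Each pairwise covariance is evaluated from the residual trait
correlation rho via a degree-5 polynomial in rho^2 with a finite-sample
correction term,

    cov ~= sum_{l=1..5} c_l rho^(2l) - (c1 / N) (1 - rho^2)^2,

using published constants ``COV_CONSTANTS``.  An independent
high-precision quadrature oracle (:func:`exact_cov_oracle`) computes the
same covariance directly from the bivariate-normal model of the two
Wald z-statistics and is used to validate the polynomial.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "COV_CONSTANTS",
    "GammaNull",
    "CombinedAssoc",
    "cov_approx",
    "exact_cov_oracle",
    "gamma_moments",
    "fisher_stat",
    "multivariate_p",
]

#: Polynomial coefficients (c1..c5) of the covariance approximation.
COV_CONSTANTS: np.ndarray = np.array([3.9081, 0.0313, 0.1022, -0.1378, 0.0941])

#: Residual correlations are clipped to this magnitude before the
#: polynomial is evaluated, guarding against rounding noise pushing an
#: estimate beyond +-1 (the polynomial itself is finite on [-1, 1]).
RHO_CLIP = 1.0


def cov_approx(rho, n_subjects=None):
    """Polynomial approximation of cov(-2 log p_r, -2 log p_r').

    Parameters
    ----------
    rho : float or array_like
        Correlation(s) between the two traits' residuals, in [-1, 1].
    n_subjects : int, optional
        Sample size for the finite-sample correction term; ``None``
        (or ``np.inf``) drops the term (the large-sample limit).

    Returns
    -------
    float or ndarray
        Approximate covariance of the two -2 log p terms.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) > 1.0):
        raise ValueError("correlation must lie in [-1, 1]")
    rho2 = rho**2
    out = np.zeros_like(rho2)
    for l, c in enumerate(COV_CONSTANTS, start=1):
        out = out + c * rho2**l
    if n_subjects is not None and np.isfinite(n_subjects):
        if n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        out = out - (COV_CONSTANTS[0] / n_subjects) * (1.0 - rho2) ** 2
    return out if out.ndim else float(out)


# --- quadrature oracle -------------------------------------------------

# Panel edges for composite Gauss-Legendre on (0, zmax]; chosen dense
# near 0 and the diagonal ridge so that even rho = 0.999 is resolved.
_PANEL_EDGES = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.5, 6.5, 9.0, 13.0)


@functools.lru_cache(maxsize=8)
def _gl_nodes(n_per_panel: int):
    x, w = np.polynomial.legendre.leggauss(n_per_panel)
    nodes, weights = [], []
    for a, b in zip(_PANEL_EDGES[:-1], _PANEL_EDGES[1:]):
        nodes.append(0.5 * (b - a) * x + 0.5 * (a + b))
        weights.append(0.5 * (b - a) * w)
    z = np.concatenate(nodes)
    wt = np.concatenate(weights)
    # g(z) = -2 log p with p = 2 Phi(-|z|), the two-sided 1-df p-value
    g = -2.0 * (np.log(2.0) + stats.norm.logsf(z))
    return z, wt, g


def exact_cov_oracle(rho: float, n_per_panel: int = 48) -> float:
    """cov(-2 log p1, -2 log p2) by high-precision 2-D quadrature.

    (Z1, Z2) is standard bivariate normal with correlation ``rho`` and
    p_j = 2 Phi(-|Z_j|) is the two-sided normal (equivalently 1-df
    chi-square) p-value.  E[-2 log p] = 2 exactly, so the covariance is
    E[g(Z1) g(Z2)] - 4.  The integrand is folded onto the positive
    quadrant (g is even), where it is smooth, and integrated with
    composite Gauss-Legendre rules; absolute error is below 1e-6 for
    |rho| <= 0.999.
    """
    rho = float(rho)
    if not abs(rho) < 1.0:
        raise ValueError("oracle requires |rho| < 1")
    a = abs(rho)  # g even in each argument => covariance even in rho
    z, wt, g = _gl_nodes(n_per_panel)
    one_m = 1.0 - a * a
    zz = z[:, None] * z[None, :]
    sq = z[:, None] ** 2 + z[None, :] ** 2
    dens = np.exp(-(sq - 2.0 * a * zz) / (2.0 * one_m)) + np.exp(
        -(sq + 2.0 * a * zz) / (2.0 * one_m)
    )
    dens *= 1.0 / (np.pi * np.sqrt(one_m))  # 2 * binormal pdf, both signs
    integrand = (g[:, None] * g[None, :]) * dens
    e_gg = float(wt @ integrand @ wt)
    return e_gg - 4.0


# --- gamma null --------------------------------------------------------


@dataclass(frozen=True)
class GammaNull:
    """Moment-matched gamma null of the Fisher statistic.

    Attributes
    ----------
    r : number of traits combined.
    n_subjects : sample size used in the finite-sample covariance term
        (``None`` for the large-sample limit).
    rho : the R x R residual-correlation matrix the null was built from.
    k, theta : gamma shape and scale; ``k * theta == 2 R``.
    """

    r: int
    n_subjects: int | None
    rho: np.ndarray = field(repr=False)
    k: float
    theta: float


def gamma_moments(rho_hat, n_subjects=None) -> GammaNull:
    """Calibrate the gamma null from a residual-correlation matrix.

    The matched variance is ``V = 4R + 2 * sum_{r<r'} cov_approx(rho_rr')``
    (each unordered trait pair contributes twice), giving
    ``theta = V / (2R)`` and ``k = (2R)^2 / V``.
    """
    rho = np.atleast_2d(np.asarray(rho_hat, dtype=float))
    r = rho.shape[0]
    if rho.shape != (r, r):
        raise ValueError("rho_hat must be square")
    if not np.allclose(rho, rho.T, atol=1e-8):
        raise ValueError("rho_hat must be symmetric")
    if not np.allclose(np.diag(rho), 1.0, atol=1e-8):
        raise ValueError("rho_hat must have unit diagonal")
    iu = np.triu_indices(r, k=1)
    off = np.clip(rho[iu], -RHO_CLIP, RHO_CLIP)
    v = 4.0 * r + 2.0 * float(np.sum(cov_approx(off, n_subjects)))
    if v <= 0.0:
        raise ValueError(
            "moment matching produced non-positive variance; "
            "cannot calibrate a gamma null"
        )
    theta = v / (2.0 * r)
    k = (2.0 * r) ** 2 / v
    n_eff = None if n_subjects is None or not np.isfinite(n_subjects) else int(n_subjects)
    return GammaNull(r=r, n_subjects=n_eff, rho=rho, k=k, theta=theta)


def fisher_stat(p=None, logp=None) -> float:
    """Fisher combination statistic xi = sum_r -2 ln p_r.

    Either raw p-values in (0, 1] or natural-log p-values (<= 0) may be
    given; the log path avoids underflow for extremely small p.
    """
    if (p is None) == (logp is None):
        raise ValueError("provide exactly one of p or logp")
    if p is not None:
        p = np.asarray(p, dtype=float)
        if np.any(p <= 0.0) or np.any(p > 1.0):
            raise ValueError("p-values must lie in (0, 1]")
        logp = np.log(p)
    else:
        logp = np.asarray(logp, dtype=float)
        if np.any(logp > 0.0):
            raise ValueError("log p-values must be <= 0")
    return float(-2.0 * np.sum(logp))


def multivariate_p(xi, null: GammaNull, log: bool = False):
    """Upper-tail probability of the gamma null at the Fisher statistic.

    With ``log=True`` the natural-log survival probability is returned,
    useful for genome-wide tails far below float underflow.
    """
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0.0):
        raise ValueError("xi must be non-negative")
    if not (null.k > 0.0 and null.theta > 0.0):
        raise ValueError("invalid gamma null parameters")
    z = xi / null.theta
    sf = special.gammaincc(null.k, z)
    if not log:
        return sf if sf.ndim else float(sf)
    with np.errstate(divide="ignore"):
        out = np.atleast_1d(np.log(sf))
    # deep tail: Q(k, z) ~ z^(k-1) e^-z / Gamma(k) * sum_j (k-1)...(k-j)/z^j
    deep = np.atleast_1d((sf < 1e-280) & (z > 0))
    if deep.any():
        zd = np.atleast_1d(z)[deep]
        k = null.k
        series = np.ones_like(zd)
        term = np.ones_like(zd)
        for j in range(1, 12):
            term = term * (k - j) / zd
            series = series + term
        out[deep] = (
            -zd + (k - 1.0) * np.log(zd) - special.gammaln(k)
            + np.log(np.maximum(series, 1e-30))
        )
    out = out.reshape(np.shape(xi))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CombinedAssoc:
    """Per-SNP combined association result."""

    snp_id: str
    xi: float
    p_multivariate: float
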