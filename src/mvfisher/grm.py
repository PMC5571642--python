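"""Genetic relationship matrix and genotype principal components.

The GRM uses the standardized (GCTA-style) estimator

    K_ij = (1/S') sum_s (g_is - 2 p_s)(g_js - 2 p_s) / (2 p_s (1 - p_s))

over the S' SNPs whose sample allele frequency clears a minor-allele
floor; p_s is the sample reference-allele frequency.  Missing dosages
are mean-imputed per SNP before standardization.  Principal components
are taken from the eigendecomposition of K (for this standardization
they agree with a genotype-matrix SVD up to scale), with scores scaled
by the square root of the eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .genotype_sim import GenotypeData

__all__ = ["GRM", "PrincipalComponents", "GRMEigen", "compute_grm", "compute_pcs",
           "spectral_decompose"]


@dataclass
class GRM:
    """N x N realized genetic relationship matrix."""

    matrix: np.ndarray
    n_snps_used: int
    subject_ids: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PrincipalComponents:
    """Top genotype PCs: scores are eigenvectors scaled by sqrt(eigenvalue)."""

    scores: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]


@dataclass
class GRMEigen:
    """Full spectral decomposition of a GRM, shared by REML fits, SNP
    tests and PCA (eigenvalues ascending, as returned by ``eigh``)."""

    values: np.ndarray
    vectors: np.ndarray = field(repr=False)
    subject_ids: np.ndarray | None = None


def compute_grm(genotypes: GenotypeData, maf_floor: float = 0.01) -> GRM:
    """Standardized-genotype GRM over SNPs passing the MAF floor."""
    if genotypes.n_subjects < 2:
        raise ValueError("GRM needs at least two subjects")
    d = genotypes.dosages.astype(float)
    d[d < 0] = np.nan  # -1 encodes missing
    col_mean = np.nanmean(d, axis=0)
    miss = np.isnan(d)
    if miss.any():
        d[miss] = np.take(col_mean, np.nonzero(miss)[1])
    p = col_mean / 2.0
    keep = (np.minimum(p, 1.0 - p) > maf_floor) & np.isfinite(p)
    if not keep.any():
        raise ValueError("no usable SNPs: all monomorphic or below the MAF floor")
    pk = p[keep]
    z = (d[:, keep] - 2.0 * pk) / np.sqrt(2.0 * pk * (1.0 - pk))
    k = (z @ z.T) / keep.sum()
    k = 0.5 * (k + k.T)
    return GRM(matrix=k, n_snps_used=int(keep.sum()),
               subject_ids=genotypes.subject_ids.copy())


def spectral_decompose(grm: GRM) -> GRMEigen:
    values, vectors = scipy.linalg.eigh(grm.matrix)
    return GRMEigen(values=values, vectors=vectors, subject_ids=grm.subject_ids)


def compute_pcs(grm: GRM, n_pcs: int = 10, eigen: GRMEigen | None = None
                ) -> PrincipalComponents:
    """Leading principal components of the GRM.

    Scores are returned eigenvalue-descending; a precomputed
    :class:`GRMEigen` is reused when available.
    """
    n = grm.n_subjects
    if not 0 < n_pcs < n:
        raise ValueError("n_pcs must be in [1, N)")
    if eigen is None:
        vals, vecs = scipy.linalg.eigh(
            grm.matrix, subset_by_index=(n - n_pcs, n - 1)
        )
    else:
        vals, vecs = eigen.values[-n_pcs:], eigen.vectors[:, -n_pcs:]
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    scores = vecs * np.sqrt(np.clip(vals, 0.0, None))[None, :]
    return PrincipalComponents(scores=scores, eigenvalues=vals)
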