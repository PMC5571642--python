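"""Shared simulated fixtures.

Cohorts are session-scoped: the 1000-subject designs with their GRM
eigendecompositions are the expensive part of most checks, and they are
read-only for every test that uses them.
"""

import numpy as np
import pytest

from mvfisher.genotype_sim import simulate_cohort
from mvfisher.grm import compute_grm, spectral_decompose


@pytest.fixture(scope="session")
def related_cohort():
    """250 families x 4 sibs, one ancestral population, 1200 SNPs."""
    return simulate_cohort("non-admixed-related", n_snps=1200, seed=11)


@pytest.fixture(scope="session")
def related_grm(related_cohort):
    return compute_grm(related_cohort)


@pytest.fixture(scope="session")
def related_eigen(related_grm):
    return spectral_decompose(related_grm)


@pytest.fixture(scope="session")
def independent_cohort():
    """1000 families x 1 child, one ancestral population, 1200 SNPs."""
    return simulate_cohort("non-admixed-independent", n_snps=1200, seed=12)


@pytest.fixture(scope="session")
def admixed_cohort():
    """1000 independent children from three parental-origin groups."""
    return simulate_cohort("admixed-independent", n_snps=1500, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
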