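"""Pedigree/admixture genotype simulator.

Cohorts are built in two stages: founder parents are drawn from one or
two ancestral populations under Hardy-Weinberg equilibrium, and child
genotypes are produced by gene dropping (one allele sampled from each
parent per SNP, Mendelian transmission of unlinked biallelic markers).

Four study designs are supported, crossing population structure with
relatedness:

* ``non-admixed-independent`` — 1000 families x 1 child, all founders
  from Population I;
* ``non-admixed-related``     — 250 families x 4 full sibs, founders
  from Population I;
* ``admixed-independent``     — 1000 x 1, parent pairs split evenly
  between Pop I x Pop I, Pop II x Pop II and Pop I x Pop II;
* ``admixed-related``         — 250 x 4 with the same origin split.

The children are the analysis sample; children from different families
are independent, sibs within a family are strongly related.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SCENARIOS",
    "PopulationFreqs",
    "Pedigree",
    "GenotypeData",
    "draw_allele_freqs",
    "simulate_parents",
    "gene_drop",
    "simulate_cohort",
]

SCENARIOS = (
    "non-admixed-independent",
    "non-admixed-related",
    "admixed-independent",
    "admixed-related",
)

#: Parent-origin labels: both founders from Pop I, both from Pop II,
#: or one from each.
ORIGINS = ("pop1", "pop2", "mixed")


@dataclass(frozen=True)
class PopulationFreqs:
    """Reference-allele frequencies of the two ancestral populations."""

    freqs_pop1: np.ndarray
    freqs_pop2: np.ndarray

    def __post_init__(self):
        if self.freqs_pop1.shape != self.freqs_pop2.shape:
            raise ValueError("both frequency vectors must have equal length")

    @property
    def n_snps(self) -> int:
        return self.freqs_pop1.shape[0]


@dataclass(frozen=True)
class Pedigree:
    """Family structure of a set of subjects.

    ``parent_indices`` holds, per subject, the row indices of the two
    parents in the founding parent sample (-1 for founders themselves).
    ``parent_origin`` is one label per family from :data:`ORIGINS`.
    """

    family_id: np.ndarray
    role: np.ndarray  # 'parent1' | 'parent2' | 'child'
    parent_indices: np.ndarray  # (N, 2), -1 for founders
    parent_origin: np.ndarray  # (n_families,)

    @property
    def n_families(self) -> int:
        return self.parent_origin.shape[0]

    def origin_of_subject(self) -> np.ndarray:
        """Per-subject family origin label."""
        return self.parent_origin[self.family_id]


@dataclass
class GenotypeData:
    """Dosage matrix (N subjects x S SNPs, 0/1/2 reference-allele copies).

    ``dosages`` may contain -1 for missing calls when read from disk;
    the simulator never produces missing data.
    """

    dosages: np.ndarray
    subject_ids: np.ndarray
    snp_ids: np.ndarray
    pedigree: Pedigree | None = None
    ref_freqs: PopulationFreqs | None = field(default=None, repr=False)
    chromosomes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        self.subject_ids = np.asarray(self.subject_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        n, s = self.dosages.shape
        if len(self.subject_ids) != n or len(self.snp_ids) != s:
            raise ValueError("id lists inconsistent with dosage matrix shape")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def draw_allele_freqs(n_snps: int, seed=None) -> PopulationFreqs:
    """Draw two independent sets of Uniform(0.1, 0.9) allele frequencies."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = _rng(seed)
    return PopulationFreqs(
        freqs_pop1=rng.uniform(0.1, 0.9, size=n_snps),
        freqs_pop2=rng.uniform(0.1, 0.9, size=n_snps),
    )


def assign_origins(n_families: int, admixed: bool) -> np.ndarray:
    """Assign parent-origin labels to families.

    Admixed designs split families into equal thirds; when the count is
    not divisible by 3 the remainder is given, in order, to pop1 then
    pop2 then mixed.  Non-admixed designs draw every founder from
    Population I.
    """
    if not admixed:
        return np.repeat("pop1", n_families).astype(object)
    base, rem = divmod(n_families, 3)
    counts = [base + (1 if i < rem else 0) for i in range(3)]
    return np.concatenate(
        [np.repeat(o, c) for o, c in zip(ORIGINS, counts)]
    ).astype(object)


def simulate_parents(
    n_families: int, admixed: bool, freqs: PopulationFreqs, seed=None
) -> tuple[GenotypeData, Pedigree]:
    """Draw founder genotypes: Binomial(2, p) per SNP within each origin."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = _rng(seed)
    origin = assign_origins(n_families, admixed)
    s = freqs.n_snps

    # parent rows interleaved: family f -> rows 2f (parent1), 2f+1 (parent2)
    pop_of_parent = np.empty((n_families, 2), dtype=object)
    pop_of_parent[:, 0] = np.where(origin == "pop2", "pop2", "pop1")
    pop_of_parent[:, 1] = np.where(origin == "pop1", "pop1", "pop2")
    pop_flat = pop_of_parent.reshape(-1)

    p = np.where(
        (pop_flat == "pop1")[:, None], freqs.freqs_pop1[None, :], freqs.freqs_pop2[None, :]
    )
    dosages = rng.binomial(2, p).astype(np.int8)

    fam = np.repeat(np.arange(n_families), 2)
    role = np.tile(np.array(["parent1", "parent2"], dtype=object), n_families)
    ids = np.array(
        [f"F{f}_{'P1' if r == 'parent1' else 'P2'}" for f, r in zip(fam, role)]
    )
    ped = Pedigree(
        family_id=fam,
        role=role,
        parent_indices=np.full((2 * n_families, 2), -1, dtype=int),
        parent_origin=origin,
    )
    geno = GenotypeData(
        dosages=dosages, subject_ids=ids, snp_ids=_snp_ids(s), pedigree=ped,
        ref_freqs=freqs,
    )
    return geno, ped


def _snp_ids(s: int) -> np.ndarray:
    return np.array([f"snp{j + 1}" for j in range(s)])


def gene_drop(
    parents: GenotypeData,
    pedigree: Pedigree,
    children_per_family: int,
    seed=None,
) -> GenotypeData:
    """Drop alleles down one generation.

    For every child and SNP, one allele is sampled uniformly from each
    parent's two alleles (a parent with dosage d transmits the reference
    allele with probability d/2); sibs are conditionally independent
    given the parents.  No phase is tracked — unlinked biallelic SNPs
    make haplotypes unnecessary.
    """
    if children_per_family < 1:
        raise ValueError("children_per_family must be >= 1")
    if np.any((parents.dosages < 0) | (parents.dosages > 2)):
        raise ValueError("parent dosages must be 0, 1 or 2 (no missing calls)")
    rng = _rng(seed)
    n_fam = pedigree.n_families
    if parents.n_subjects != 2 * n_fam:
        raise ValueError("malformed pedigree: expected two parents per family")

    c = children_per_family
    p1 = parents.dosages[0::2].astype(float) / 2.0  # (F, S)
    p2 = parents.dosages[1::2].astype(float) / 2.0
    trans1 = rng.binomial(1, np.repeat(p1, c, axis=0))
    trans2 = rng.binomial(1, np.repeat(p2, c, axis=0))
    dosages = (trans1 + trans2).astype(np.int8)

    fam = np.repeat(np.arange(n_fam), c)
    within = np.tile(np.arange(1, c + 1), n_fam)
    ids = np.array([f"F{f}_C{k}" for f, k in zip(fam, within)])
    par_idx = np.stack([2 * fam, 2 * fam + 1], axis=1)
    ped = Pedigree(
        family_id=fam,
        role=np.repeat("child", n_fam * c).astype(object),
        parent_indices=par_idx,
        parent_origin=pedigree.parent_origin,
    )
    return GenotypeData(
        dosages=dosages, subject_ids=ids, snp_ids=parents.snp_ids, pedigree=ped,
        ref_freqs=parents.ref_freqs,
    )


def simulate_cohort(
    scenario: str,
    n_snps: int = 10_000,
    seed=None,
    freqs: PopulationFreqs | None = None,
    include_parents: bool = False,
) -> GenotypeData:
    """Simulate a children-only analysis cohort of N = 1000 subjects.

    Independent designs use 1000 families with one child each; related
    designs use 250 families of four full sibs.  Parental genotypes are
    discarded unless ``include_parents`` is set (not part of the
    standard designs).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    rng = _rng(seed)
    admixed = scenario.startswith("admixed")
    related = scenario.endswith("related") and not scenario.endswith("unrelated")
    n_families, children = (250, 4) if related else (1000, 1)

    if freqs is None:
        freqs = draw_allele_freqs(n_snps, rng)
    parents, ped = simulate_parents(n_families, admixed, freqs, rng)
    children_data = gene_drop(parents, ped, children, rng)
    if not include_parents:
        return children_data
    dosages = np.vstack([children_data.dosages, parents.dosages])
    ids = np.concatenate([children_data.subject_ids, parents.subject_ids])
    ped_all = Pedigree(
        family_id=np.concatenate([children_data.pedigree.family_id, ped.family_id]),
        role=np.concatenate([children_data.pedigree.role, ped.role]),
        parent_indices=np.vstack(
            [children_data.pedigree.parent_indices, ped.parent_indices]
        ),
        parent_origin=ped.parent_origin,
    )
    return GenotypeData(
        dosages=dosages, subject_ids=ids, snp_ids=parents.snp_ids,
        pedigree=ped_all, ref_freqs=freqs,
    )
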