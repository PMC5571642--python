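"""Founder sampling, gene dropping and cohort designs."""

import numpy as np
import pytest

from mvfisher.genotype_sim import (
    SCENARIOS,
    GenotypeData,
    Pedigree,
    PopulationFreqs,
    assign_origins,
    draw_allele_freqs,
    gene_drop,
    simulate_cohort,
    simulate_parents,
)


def _toy_parents(dosage_pairs, n_snps=1):
    """Parents with fixed dosages at every SNP, one family per pair."""
    f = len(dosage_pairs)
    d = np.repeat(np.asarray(dosage_pairs, dtype=np.int8).reshape(-1, 1),
                  n_snps, axis=1)
    ped = Pedigree(
        family_id=np.repeat(np.arange(f), 2),
        role=np.tile(np.array(["parent1", "parent2"], dtype=object), f),
        parent_indices=np.full((2 * f, 2), -1),
        parent_origin=np.repeat("pop1", f).astype(object),
    )
    geno = GenotypeData(
        dosages=d,
        subject_ids=np.array([f"P{i}" for i in range(2 * f)]),
        snp_ids=np.array([f"snp{j}" for j in range(n_snps)]),
        pedigree=ped,
    )
    return geno, ped


class TestAlleleFreqs:
    def test_bounds_and_mean(self):
        freqs = draw_allele_freqs(10_000, seed=1)
        for v in (freqs.freqs_pop1, freqs.freqs_pop2):
            assert v.min() > 0.1 and v.max() < 0.9
            assert abs(v.mean() - 0.5) < 0.02

    def test_single_snp(self):
        freqs = draw_allele_freqs(1, seed=7)
        assert freqs.n_snps == 1
        assert 0.1 < freqs.freqs_pop1[0] < 0.9

    def test_seeded_determinism(self):
        a, b = draw_allele_freqs(50, seed=3), draw_allele_freqs(50, seed=3)
        np.testing.assert_array_equal(a.freqs_pop1, b.freqs_pop1)
        np.testing.assert_array_equal(a.freqs_pop2, b.freqs_pop2)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            draw_allele_freqs(0)


class TestOriginAssignment:
    @pytest.mark.parametrize(
        "n, expected",
        [(300, (100, 100, 100)), (301, (101, 100, 100)), (302, (101, 101, 100))],
    )
    def test_thirds_with_deterministic_remainder(self, n, expected):
        origins = assign_origins(n, admixed=True)
        counts = tuple(int((origins == o).sum()) for o in ("pop1", "pop2", "mixed"))
        assert counts == expected

    def test_non_admixed_single_population(self):
        assert set(assign_origins(10, admixed=False)) == {"pop1"}


class TestSimulateParents:
    def test_non_admixed_frequencies_track_population(self):
        freqs = draw_allele_freqs(500, seed=2)
        parents, ped = simulate_parents(300, admixed=False, freqs=freqs, seed=4)
        assert parents.n_subjects == 600
        assert set(ped.parent_origin) == {"pop1"}
        p_hat = parents.dosages.mean(axis=0) / 2.0
        p = freqs.freqs_pop1
        band = 5.0 * np.sqrt(p * (1 - p) / (2 * 600))
        assert np.mean(np.abs(p_hat - p) < band) > 0.99

    def test_low_frequency_mean_dosage(self):
        s = 2000
        freqs = PopulationFreqs(np.full(s, 0.1), np.full(s, 0.1))
        parents, _ = simulate_parents(5, admixed=False, freqs=freqs, seed=0)
        assert parents.dosages.mean() == pytest.approx(0.2, abs=0.02)

    def test_invalid_family_count(self):
        with pytest.raises(ValueError):
            simulate_parents(0, False, draw_allele_freqs(2, seed=0))


class TestGeneDrop:
    def test_forced_heterozygote(self):
        parents, ped = _toy_parents([(2, 0)], n_snps=20)
        kids = gene_drop(parents, ped, 3, seed=0)
        assert np.all(kids.dosages == 1)

    def test_het_by_het_transmission_distribution(self):
        # enumerate the 4 equiprobable transmissions of two AB parents:
        # child dosage 0/1/2 with probability 1/4, 1/2, 1/4
        expected = np.array([0.25, 0.5, 0.25])
        parents, ped = _toy_parents([(1, 1)], n_snps=6000)
        kids = gene_drop(parents, ped, 1, seed=5)
        observed = np.bincount(kids.dosages.ravel(), minlength=3) / 6000
        assert np.allclose(observed, expected, atol=0.03)

    def test_sibs_share_half_their_genome(self):
        freqs = draw_allele_freqs(4000, seed=6)
        parents, ped = simulate_parents(80, admixed=False, freqs=freqs, seed=7)
        kids = gene_drop(parents, ped, 2, seed=8)
        p = freqs.freqs_pop1
        z = (kids.dosages - 2 * p) / np.sqrt(2 * p * (1 - p))
        corr = np.mean(z[0::2] * z[1::2], axis=1)  # per sib pair, across SNPs
        assert corr.mean() == pytest.approx(0.5, abs=0.05)

    def test_missing_parent_rejected(self):
        parents, ped = _toy_parents([(1, 1)])
        bad = Pedigree(
            family_id=ped.family_id,
            role=ped.role,
            parent_indices=ped.parent_indices,
            parent_origin=np.repeat("pop1", 3).astype(object),  # 3 fams, 2 parents
        )
        with pytest.raises(ValueError):
            gene_drop(parents, bad, 1, seed=0)


class TestSimulateCohort:
    def test_design_shapes(self):
        related = simulate_cohort("admixed-related", n_snps=50, seed=1)
        assert related.n_subjects == 1000
        assert related.pedigree.n_families == 250
        assert np.all(np.bincount(related.pedigree.family_id) == 4)
        indep = simulate_cohort("non-admixed-independent", n_snps=50, seed=1)
        assert indep.pedigree.n_families == 1000

    def test_entries_are_valid_dosages(self):
        coh = simulate_cohort("admixed-independent", n_snps=100, seed=2)
        assert set(np.unique(coh.dosages)) <= {0, 1, 2}

    def test_seeded_determinism(self):
        a = simulate_cohort("non-admixed-related", n_snps=60, seed=9)
        b = simulate_cohort("non-admixed-related", n_snps=60, seed=9)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            simulate_cohort("panmictic", n_snps=10, seed=0)

    def test_include_parents_extends_sample(self):
        coh = simulate_cohort("non-admixed-related", n_snps=20, seed=3,
                              include_parents=True)
        assert coh.n_subjects == 1000 + 500

    def test_all_scenarios_run(self):
        for s in SCENARIOS:
            assert simulate_cohort(s, n_snps=10, seed=0).n_subjects == 1000


def test_children_in_hardy_weinberg_proportions(independent_cohort):
    """Unrelated non-admixed children sit in HWE at the drawn p_s."""
    from scipy.stats import chi2

    coh = independent_cohort
    p = coh.ref_freqs.freqs_pop1
    n = coh.n_subjects
    counts = np.stack([(coh.dosages == d).sum(axis=0) for d in (0, 1, 2)])
    expected = np.stack([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
    stat = ((counts - expected) ** 2 / expected).sum(axis=0)
    pvals = chi2.sf(stat, df=2)
    assert np.mean(pvals > 0.001) >= 0.99
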