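"""Generators: pedigrees, gene-dropped genotypes, logit-normal
methylation, mixed-model phenotypes."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import logit

from aspuw.exceptions import ValidationError
from aspuw.simulate import (
    EffectSpec,
    PedigreeSpec,
    simulate_dataset,
    simulate_genotypes,
    simulate_methylation,
    simulate_pedigree,
    simulate_phenotype,
)


class TestPedigree:
    def test_single_sample_kinship_is_identity(self):
        ped = simulate_pedigree(PedigreeSpec(1, 1, seed=0))
        assert ped.kinship.shape == (1, 1)
        assert ped.kinship[0, 0] == 1.0

    def test_families_are_independent_blocks(self):
        ped = simulate_pedigree(PedigreeSpec(2, 3, seed=0))
        fam = ped.samples.family_ids
        cross = fam[:, None] != fam[None, :]
        assert np.all(ped.kinship[cross] == 0.0)

    def test_nuclear_family_relationship_coefficients(self):
        """Enumerate pairs by relationship class in 100 families of 4."""
        ped = simulate_pedigree(PedigreeSpec(100, 4, seed=1))
        kin = ped.kinship
        n = ped.n
        assert np.allclose(np.diag(kin), 1.0)
        for i in range(n):
            for j in range(i + 1, n):
                same_family = ped.samples.family_ids[i] == ped.samples.family_ids[j]
                if not same_family:
                    expected = 0.0
                else:
                    i_child = ped.father[i] >= 0
                    j_child = ped.father[j] >= 0
                    # spouses unrelated; parent-offspring and sibs 0.5
                    expected = 0.0 if not (i_child or j_child) else 0.5
                assert kin[i, j] == expected

    def test_kinship_symmetric_psd_unit_diagonal(self):
        ped = simulate_pedigree(PedigreeSpec(10, (3, 4, 5), seed=2))
        kin = ped.kinship
        assert np.array_equal(kin, kin.T)
        assert np.linalg.eigvalsh(kin)[0] > -1e-10
        assert np.allclose(np.diag(kin), 1.0)

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValidationError):
            PedigreeSpec(0, 4)
        with pytest.raises(ValidationError):
            PedigreeSpec(3, 0)

    def test_reproducible(self):
        a = simulate_pedigree(PedigreeSpec(5, (2, 4), seed=9))
        b = simulate_pedigree(PedigreeSpec(5, (2, 4), seed=9))
        assert np.array_equal(a.kinship, b.kinship)
        assert a.samples.data.equals(b.samples.data)


class TestGenotypes:
    def test_founder_hardy_weinberg_at_half(self):
        ped = simulate_pedigree(PedigreeSpec(1, 1, seed=0))
        geno = simulate_genotypes(ped, 20000, maf_range=(0.5, 0.5), seed=1)
        counts = np.bincount(geno.values.astype(int).ravel(), minlength=3) / 20000
        assert np.allclose(counts, [0.25, 0.5, 0.25], atol=0.02)

    def test_values_are_additive_codes(self):
        ped = simulate_pedigree(PedigreeSpec(5, 4, seed=0))
        geno = simulate_genotypes(ped, 100, seed=1)
        assert set(np.unique(geno.values)) <= {0.0, 1.0, 2.0}

    def test_sib_standardized_crossproduct_near_half(self):
        """Mean realized genotype relatedness between sibs ~ 0.5."""
        ped = simulate_pedigree(PedigreeSpec(100, 4, seed=3))
        geno = simulate_genotypes(ped, 5000, seed=4)
        G = geno.values
        p = G.mean(axis=0) / 2
        keep = (p > 0.02) & (p < 0.98)
        Z = (G[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        sib_vals = []
        for f in range(100):
            i, j = 4 * f + 2, 4 * f + 3
            sib_vals.append(Z[i] @ Z[j] / Z.shape[1])
        assert abs(np.mean(sib_vals) - 0.5) < 0.05

    def test_maf_range_validated(self):
        ped = simulate_pedigree(PedigreeSpec(1, 2, seed=0))
        with pytest.raises(ValidationError):
            simulate_genotypes(ped, 10, maf_range=(0.0, 0.5))
        with pytest.raises(ValidationError):
            simulate_genotypes(ped, 10, maf_range=(0.1, 0.7))


class TestMethylation:
    def test_values_in_unit_interval(self):
        meth = simulate_methylation(50, 8, seed=0)
        assert meth.values.min() >= 0.0 and meth.values.max() <= 1.0

    def test_zero_correlation_gives_independent_cpgs(self):
        meth = simulate_methylation(3000, 6, within_gene_corr=0.0, seed=1)
        corr = np.corrcoef(meth.values.T)
        off = corr[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.08

    def test_latent_correlation_recovered(self):
        """rho = 0.5, p = 10, n = 2000: mean off-diagonal latent
        correlation (logit scale) recovers 0.5 within 0.05."""
        meth = simulate_methylation(2000, 10, within_gene_corr=0.5, seed=2)
        z = logit(meth.values)
        corr = np.corrcoef(z.T)
        off = corr[~np.eye(10, dtype=bool)]
        assert abs(off.mean() - 0.5) < 0.05

    def test_variance_profile_tracked(self):
        profile = np.array([0.02, 0.05, 0.1, 0.2])
        meth = simulate_methylation(4000, 4, variance_profile=profile, seed=3)
        sds = meth.values.std(axis=0, ddof=1)
        assert np.allclose(sds, profile, rtol=0.1)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValidationError):
            simulate_methylation(10, 2, within_gene_corr=1.0)


class TestPhenotype:
    def test_pure_noise_case_is_iid_gaussian(self):
        ped = simulate_pedigree(PedigreeSpec(200, 4, seed=0))
        meth = simulate_methylation(ped.n, 3, seed=1)
        eff = EffectSpec(alpha=np.zeros(3), beta=np.zeros(3), tau=[0.0],
                         sigma2=1.0)
        y = simulate_phenotype(ped.samples, meth, eff, [ped.kinship], seed=2)
        assert stats.kstest(y, "norm").pvalue > 0.01

    def test_sib_covariance_matches_variance_component(self):
        """T1 = 0.5 on sib kinship 0.5 -> phenotype covariance ~ 0.25."""
        ped = simulate_pedigree(PedigreeSpec(150, 4, seed=3))
        meth = simulate_methylation(ped.n, 2, seed=4)
        eff = EffectSpec(alpha=np.zeros(3), beta=np.zeros(2), tau=[0.5],
                         sigma2=1.0)
        prods = []
        for r in range(60):
            y = simulate_phenotype(ped.samples, meth, eff, [ped.kinship], seed=100 + r)
            sib1 = y[2::4]
            sib2 = y[3::4]
            prods.append(np.mean(sib1 * sib2))
        assert abs(np.mean(prods) - 0.25) < 0.05

    def test_dimension_mismatch_rejected(self):
        ped = simulate_pedigree(PedigreeSpec(2, 2, seed=0))
        meth = simulate_methylation(ped.n, 2, seed=0)
        eff = EffectSpec(alpha=np.zeros(3), beta=np.zeros(5), tau=[0.1],
                         sigma2=1.0)
        with pytest.raises(ValidationError):
            simulate_phenotype(ped.samples, meth, eff, [ped.kinship], seed=0)

    def test_bit_reproducible(self):
        ped = simulate_pedigree(PedigreeSpec(3, 4, seed=5))
        meth = simulate_methylation(ped.n, 4, seed=6)
        eff = EffectSpec(alpha=np.zeros(3), beta=np.zeros(4), tau=[0.3],
                         sigma2=1.0)
        y1 = simulate_phenotype(ped.samples, meth, eff, [ped.kinship], seed=7)
        y2 = simulate_phenotype(ped.samples, meth, eff, [ped.kinship], seed=7)
        assert np.array_equal(y1, y2)


class TestDataset:
    def test_gene_blocks_are_independent(self):
        """Correlation is within-gene only: CpGs of different genes are
        (near) uncorrelated even with high within-gene correlation."""
        data = simulate_dataset(n_families=300, n_genes=2, cpgs_per_gene=4,
                                within_gene_corr=0.6, m_snps=50, seed=8)
        z = logit(data["methylation"].values)
        corr = np.corrcoef(z.T)
        within_a = corr[:4, :4][~np.eye(4, dtype=bool)]
        across = corr[:4, 4:]
        assert within_a.mean() > 0.4
        assert np.abs(across).mean() < 0.08

    def test_causal_effects_enter_phenotype(self):
        causal = {"gene0001": np.full(3, 2.0)}
        a = simulate_dataset(n_families=50, n_genes=3, cpgs_per_gene=3,
                             causal_genes=causal, m_snps=50, seed=9)
        b = simulate_dataset(n_families=50, n_genes=3, cpgs_per_gene=3,
                             m_snps=50, seed=9)
        G = a["methylation"].values[:, 3:6]
        diff = a["samples"].endog - b["samples"].endog
        assert np.allclose(diff, G @ np.full(3, 2.0))
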