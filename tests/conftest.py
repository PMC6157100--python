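import numpy as np
import pytest

from aspuw.model import FamilyMixedLM
from aspuw.relatedness import VarianceComponentSet, compute_grm, family_block_matrix
from aspuw.simulate import (
    EffectSpec,
    PedigreeSpec,
    simulate_genotypes,
    simulate_methylation,
    simulate_pedigree,
    simulate_phenotype,
)


@pytest.fixture(scope="session")
def small_design():
    """40 nuclear families of 4 with estimated GRM, family blocks and a
    10-CpG methylation block; shared across tests that only need a
    valid, modest-sized design."""
    ped = simulate_pedigree(PedigreeSpec(n_families=40, family_size=4, seed=11))
    geno = simulate_genotypes(ped, m_snps=800, seed=12)
    grm = compute_grm(geno)
    blocks = family_block_matrix(ped.samples.family_ids)
    vc = VarianceComponentSet([grm, blocks], ["grm", "family"])
    meth = simulate_methylation(ped.n, 10, within_gene_corr=0.4, seed=13)
    return ped, geno, meth, vc


@pytest.fixture(scope="session")
def null_fit(small_design):
    """A converged null-model fit on a null phenotype."""
    ped, _, meth, vc = small_design
    effects = EffectSpec(
        alpha=[1.0, 0.02, 0.5], beta=np.zeros(meth.p), tau=[0.3, 0.2], sigma2=1.0
    )
    y = simulate_phenotype(ped.samples, meth, effects, vc.psis, seed=14)
    fit = FamilyMixedLM(y, ped.samples.exog, vc).fit()
    return fit, ped, meth, vc, y
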