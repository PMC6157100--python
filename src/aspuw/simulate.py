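"""Synthetic family methylation studies.

Everything downstream of raw data — GRM estimation, the null mixed
model, the SPUw/aSPUw tests, the genome scan — is testable end-to-end on
data from this module, with no external download:

* nuclear-family pedigrees with the exact additive relationship matrix;
* SNP genotypes by gene-dropping (founders at Hardy–Weinberg, Mendelian
  transmission to offspring), so realized relatedness matches the
  pedigree in expectation;
* CpG beta-values in [0, 1] from a logit-normal latent model with
  exchangeable within-gene correlation and heterogeneous per-CpG
  variances (the heterogeneity is what separates weighted from
  unweighted tests);
* phenotypes from the linear mixed model
  ``y = X a + G b + u + e``, ``u ~ N(0, sum_k T_k Psi_k)``,
  ``e ~ iid N(0, sigma^2)`` — with ``b = 0`` an exact null generator.

All generators are bit-reproducible given the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._seeds import derive_rng
from .exceptions import ValidationError
from .io import GeneAnnotation, GenotypeMatrix, MethylationMatrix, SampleFrame

__all__ = [
    "PedigreeSpec",
    "EffectSpec",
    "Pedigree",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_methylation",
    "simulate_phenotype",
    "simulate_dataset",
]


@dataclass(frozen=True)
class PedigreeSpec:
    """Layout of a multi-family sample.

    ``family_size`` is either a fixed size or a sequence of candidate
    sizes sampled uniformly per family.  Families are nuclear: sizes 1
    and 2 are founders only; size s >= 3 is two founder parents plus
    s - 2 children.
    """

    n_families: int
    family_size: int | Sequence[int] = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 1:
            raise ValidationError("n_families must be >= 1")
        sizes = (
            [self.family_size]
            if isinstance(self.family_size, (int, np.integer))
            else list(self.family_size)
        )
        if not sizes or any(int(s) < 1 for s in sizes):
            raise ValidationError("family sizes must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """Fixed effects, CpG effects and variance components of the
    phenotype model."""

    alpha: np.ndarray  # q covariate effects
    beta: np.ndarray  # p CpG effects (any sign)
    tau: np.ndarray  # K variance components, >= 0
    sigma2: float  # residual variance, > 0

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.atleast_1d(np.asarray(self.alpha, float)))
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))
        object.__setattr__(self, "tau", np.atleast_1d(np.asarray(self.tau, float)))
        if (self.tau < 0).any():
            raise ValidationError("variance components must be nonnegative")
        if not self.sigma2 > 0:
            raise ValidationError("residual variance must be positive")


@dataclass
class Pedigree:
    """Pedigree realization: sample frame, parent pointers and the exact
    additive relationship (kinship-scaled) matrix."""

    samples: SampleFrame
    father: np.ndarray  # index of father, -1 for founders
    mother: np.ndarray
    kinship: np.ndarray  # n x n, unit diagonal, symmetric PSD

    @property
    def n(self) -> int:
        return self.samples.n


def simulate_pedigree(spec: PedigreeSpec) -> Pedigree:
    """Generate nuclear families with covariates and the true kinship.

    Relatedness uses standard coefficients: 0.5 for parent–offspring and
    full siblings, 0 across families and between the two founders.
    Covariates are an intercept, a continuous age-like variable and a
    binary sex-like variable.
    """
    rng = derive_rng(spec.seed, "pedigree")
    sizes = (
        [int(spec.family_size)] * spec.n_families
        if isinstance(spec.family_size, (int, np.integer))
        else list(rng.choice(list(spec.family_size), size=spec.n_families))
    )
    n = int(sum(sizes))
    father = np.full(n, -1, dtype=int)
    mother = np.full(n, -1, dtype=int)
    kin = np.eye(n)
    sample_id, family_id = [], []
    pos = 0
    for f, s in enumerate(sizes):
        idx = np.arange(pos, pos + s)
        for j, i in enumerate(idx):
            sample_id.append(f"F{f:04d}_I{j}")
            family_id.append(f"F{f:04d}")
        if s >= 3:
            p1, p2 = idx[0], idx[1]
            children = idx[2:]
            for c in children:
                father[c], mother[c] = p1, p2
                kin[c, p1] = kin[p1, c] = 0.5
                kin[c, p2] = kin[p2, c] = 0.5
            for a in children:
                for b in children:
                    if a != b:
                        kin[a, b] = 0.5
        pos += s

    age = rng.uniform(20.0, 70.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    data = pd.DataFrame(
        {
            "sample_id": sample_id,
            "family_id": family_id,
            "intercept": 1.0,
            "age": age,
            "sex": sex,
        }
    )
    frame = SampleFrame(data, ["intercept", "age", "sex"])
    return Pedigree(frame, father, mother, kin)


def simulate_genotypes(
    pedigree: Pedigree,
    m_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypeMatrix:
    """SNP genotypes by gene-dropping through the pedigree.

    Founder alleles are Bernoulli draws at each SNP's minor allele
    frequency (Hardy–Weinberg); each child inherits one uniformly chosen
    allele from each parent, independently per SNP.
    """
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0.0 < lo <= hi <= 0.5):
        raise ValidationError("maf_range must be within (0, 0.5]")
    if m_snps < 1:
        raise ValidationError("m_snps must be >= 1")
    rng = derive_rng(seed, "genotypes")
    n = pedigree.n
    maf = rng.uniform(lo, hi, size=m_snps)
    # haplotypes: n x 2 x m
    H = np.zeros((n, 2, m_snps), dtype=np.int8)
    for i in range(n):
        fa, mo = pedigree.father[i], pedigree.mother[i]
        if fa < 0:
            H[i] = rng.random((2, m_snps)) < maf
        else:
            pick_f = rng.integers(0, 2, size=m_snps)
            pick_m = rng.integers(0, 2, size=m_snps)
            cols = np.arange(m_snps)
            H[i, 0] = H[fa, pick_f, cols]
            H[i, 1] = H[mo, pick_m, cols]
    values = H.sum(axis=1).astype(float)
    snp_ids = np.array([f"snp{s:06d}" for s in range(m_snps)])
    return GenotypeMatrix(values, snp_ids, pedigree.samples.sample_ids)


def _latent_scale_for_sd(target_sd: float, nodes=None) -> float:
    """Scale a of the logit-normal expit(a Z), Z ~ N(0,1), whose standard
    deviation equals ``target_sd`` (must lie in (0, 0.5))."""
    if not 0.0 < target_sd < 0.5:
        raise ValidationError("per-CpG target SD must be in (0, 0.5)")
    if nodes is None:
        nodes = np.polynomial.hermite_e.hermegauss(81)
    x, w = nodes
    w = w / w.sum()

    def sd_of(a):
        vals = expit(a * x)
        m = float(w @ vals)
        return float(np.sqrt(max(w @ vals**2 - m * m, 0.0)))

    return brentq(lambda a: sd_of(a) - target_sd, 1e-9, 1e4, xtol=1e-10)


def simulate_methylation(
    n: int,
    p_cpgs: int,
    within_gene_corr: float = 0.3,
    variance_profile: np.ndarray | None = None,
    seed: int = 0,
    rng_key: str = "methylation",
    cpg_ids: Sequence[str] | None = None,
    chrom: str = "chr1",
    positions: np.ndarray | None = None,
) -> MethylationMatrix:
    """Correlated beta-values from a logit-normal latent model.

    Latent Gaussians have exchangeable correlation ``within_gene_corr``
    across CpGs within a sample; each CpG j is mapped through
    ``expit(a_j z)`` with ``a_j`` calibrated (Gauss–Hermite quadrature)
    so the population SD of CpG j equals ``variance_profile[j]``.
    Values therefore always lie in (0, 1) and are centred at 0.5.

    ``variance_profile`` entries are target standard deviations in
    (0, 0.5); the default spreads them over [0.02, 0.2] so that
    variance-weighted and constant-weight tests genuinely differ.
    """
    rho = float(within_gene_corr)
    if not 0.0 <= rho < 1.0:
        raise ValidationError("within_gene_corr must be in [0, 1)")
    if n < 1 or p_cpgs < 1:
        raise ValidationError("dimensions must be positive")
    if variance_profile is None:
        variance_profile = np.geomspace(0.02, 0.2, p_cpgs)
    variance_profile = np.asarray(variance_profile, float)
    if variance_profile.shape != (p_cpgs,) or (variance_profile <= 0).any():
        raise ValidationError("variance_profile must be a positive p-vector")

    rng = derive_rng(seed, rng_key)
    shared = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, p_cpgs))
    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise

    nodes = np.polynomial.hermite_e.hermegauss(81)
    scales = np.array([_latent_scale_for_sd(s, nodes) for s in variance_profile])
    values = expit(z * scales)

    if cpg_ids is None:
        cpg_ids = [f"cg{j:06d}" for j in range(p_cpgs)]
    if positions is None:
        positions = np.arange(p_cpgs) * 100 + 1000
    manifest = pd.DataFrame(
        {"cpg_id": list(cpg_ids), "chrom": chrom, "pos": np.asarray(positions, int)}
    )
    sample_ids = np.array([f"S{i:05d}" for i in range(n)])
    return MethylationMatrix(values, manifest, sample_ids)


def simulate_phenotype(
    frame: SampleFrame,
    meth: MethylationMatrix,
    effects: EffectSpec,
    psis: Sequence[np.ndarray],
    seed: int = 0,
) -> np.ndarray:
    """Draw ``y = X a + G b + u + e`` from the mixed model.

    ``u ~ N(0, sum_k tau_k Psi_k)`` and ``e ~ iid N(0, sigma2)``.  With
    ``beta = 0`` this is an exact draw from the null model.
    """
    X = frame.exog
    G = meth.values
    n = frame.n
    if effects.alpha.shape != (X.shape[1],):
        raise ValidationError("alpha length does not match covariate count")
    if effects.beta.shape != (G.shape[1],):
        raise ValidationError("beta length does not match CpG count")
    psis = [np.asarray(p, float) for p in psis]
    if effects.tau.shape != (len(psis),):
        raise ValidationError("tau length does not match number of Psi matrices")
    for p in psis:
        if p.shape != (n, n):
            raise ValidationError("Psi dimension does not match sample count")
    if G.shape[0] != n:
        raise ValidationError("methylation rows do not match sample count")

    rng = derive_rng(seed, "phenotype")
    mean = X @ effects.alpha + G @ effects.beta
    y = mean + rng.standard_normal(n) * np.sqrt(effects.sigma2)
    cov = sum(t * p for t, p in zip(effects.tau, psis)) if psis else None
    if cov is not None and effects.tau.sum() > 0:
        vals, vecs = np.linalg.eigh(cov)
        vals = np.clip(vals, 0.0, None)
        y = y + (vecs * np.sqrt(vals)) @ rng.standard_normal(n)
    return y


def simulate_dataset(
    n_families: int = 100,
    family_size: int | Sequence[int] = 4,
    n_genes: int = 20,
    cpgs_per_gene: int | Sequence[int] = 5,
    m_snps: int = 2000,
    within_gene_corr: float = 0.3,
    tau: Sequence[float] = (0.3, 0.2),
    sigma2: float = 1.0,
    alpha: Sequence[float] = (1.0, 0.02, 0.5),
    causal_genes: dict | None = None,
    seed: int = 0,
):
    """Build a complete synthetic study: pedigree, genotypes, methylation
    with a gene map, and a phenotype.

    ``causal_genes`` maps gene_id -> p-vector of CpG effects for that
    gene (all other genes have beta = 0).  ``tau`` holds the variance
    components on (kinship, family-block) in that order.  Returns a dict
    with keys ``samples``, ``pedigree``, ``genotypes``, ``methylation``,
    ``genes``, ``truth``.
    """
    ped = simulate_pedigree(PedigreeSpec(n_families, family_size, seed=seed))
    geno = simulate_genotypes(ped, m_snps, seed=seed + 1)

    per_gene = (
        [int(cpgs_per_gene)] * n_genes
        if isinstance(cpgs_per_gene, (int, np.integer))
        else list(cpgs_per_gene)
    )
    p_total = int(sum(per_gene))
    rng = derive_rng(seed, "dataset-layout")
    profile = rng.uniform(0.02, 0.2, size=p_total)

    genes, cpg_ids, positions = [], [], []
    pos = 0
    gene_start = 1000
    for g, p_g in enumerate(per_gene):
        gid = f"gene{g:04d}"
        start = gene_start
        end = start + p_g * 100 + 50
        genes.append(GeneAnnotation(gid, "chr1", start, end))
        for j in range(p_g):
            cpg_ids.append(f"{gid}_cg{j}")
            positions.append(start + 10 + j * 100)
        gene_start = end + 500  # gap so no CpG falls between genes' intervals
        pos += p_g

    # correlation is exchangeable WITHIN a gene only: each gene's CpG block
    # gets its own latent shared factor, independent across genes
    blocks = []
    off = 0
    for g, p_g in zip(genes, per_gene):
        blocks.append(
            simulate_methylation(
                ped.n,
                p_g,
                within_gene_corr=within_gene_corr,
                variance_profile=profile[off : off + p_g],
                seed=seed + 2,
                rng_key=g.gene_id,
                cpg_ids=cpg_ids[off : off + p_g],
                positions=np.array(positions[off : off + p_g]),
            ).values
        )
        off += p_g
    manifest = pd.DataFrame(
        {"cpg_id": cpg_ids, "chrom": "chr1", "pos": np.asarray(positions, int)}
    )
    meth = MethylationMatrix(np.hstack(blocks), manifest, ped.samples.sample_ids)

    beta = np.zeros(p_total)
    if causal_genes:
        offsets = dict()
        off = 0
        for g, p_g in zip(genes, per_gene):
            offsets[g.gene_id] = (off, off + p_g)
            off += p_g
        for gid, b in causal_genes.items():
            lo, hi = offsets[gid]
            b = np.asarray(b, float)
            if b.shape != (hi - lo,):
                raise ValidationError(f"effect vector for {gid} has wrong length")
            beta[lo:hi] = b

    from .relatedness import family_block_matrix  # local import avoids cycle

    psis = [ped.kinship, family_block_matrix(ped.samples.family_ids)]
    effects = EffectSpec(alpha=np.asarray(alpha, float), beta=beta, tau=np.asarray(tau, float), sigma2=sigma2)
    y = simulate_phenotype(ped.samples, meth, effects, psis, seed=seed + 3)
    samples = ped.samples.with_phenotype(y)

    truth = {
        "seed": seed,
        "n_families": n_families,
        "family_size": family_size if isinstance(family_size, int) else list(family_size),
        "tau": list(map(float, tau)),
        "sigma2": float(sigma2),
        "alpha": list(map(float, alpha)),
        "causal_genes": {k: list(map(float, v)) for k, v in (causal_genes or {}).items()},
    }
    return {
        "samples": samples,
        "pedigree": ped,
        "genotypes": geno,
        "methylation": meth,
        "genes": genes,
        "truth": truth,
    }
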