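"""Construction of the prespecified random-effect covariance structures.

Two structures are used genome-wide:

* ``compute_grm`` — the empirical genetic relationship matrix (GRM)
  estimated from SNP genotypes, capturing realized genetic relatedness;
* ``family_block_matrix`` — a block matrix of ones within each family,
  capturing a shared-environment effect.

Both enter the null mixed model as prespecified correlation matrices
Psi_k whose scalar variance components T_k are estimated by REML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ComputationError, ValidationError
from .io import GenotypeMatrix

__all__ = ["VarianceComponentSet", "compute_grm", "family_block_matrix", "psd_repair"]

PSD_TOL = 1e-8


def psd_repair(matrix: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    """Symmetrize and clip negative eigenvalues at zero.

    Eigenvalues below ``-tol`` are still clipped (the result is the
    nearest PSD matrix in Frobenius norm); callers that want strictness
    should check beforehand.
    """
    sym = 0.5 * (matrix + matrix.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals[0] >= 0:
        return sym
    vals = np.clip(vals, 0.0, None)
    out = (vecs * vals) @ vecs.T
    return 0.5 * (out + out.T)


@dataclass
class VarianceComponentSet:
    """The K prespecified n x n PSD matrices Psi_k with their labels.

    ``tau`` (the fitted variance components T_k) and ``sigma2`` (the
    residual variance) are populated by the null-model fit.
    """

    psis: list[np.ndarray]
    labels: list[str]
    tau: np.ndarray | None = field(default=None)
    sigma2: float | None = field(default=None)

    def __post_init__(self):
        if len(self.psis) != len(self.labels):
            raise ValidationError("psis and labels must have equal length")
        if len(self.psis) < 1:
            raise ValidationError("at least one variance-component matrix required")
        checked = []
        for lab, psi in zip(self.labels, self.psis):
            psi = np.asarray(psi, float)
            if psi.ndim != 2 or psi.shape[0] != psi.shape[1]:
                raise ValidationError(f"Psi {lab!r} is not square")
            if not np.allclose(psi, psi.T, atol=1e-10):
                raise ValidationError(f"Psi {lab!r} is not symmetric")
            w = np.linalg.eigvalsh(psi)
            if w[0] < -PSD_TOL:
                raise ValidationError(
                    f"Psi {lab!r} has eigenvalue {w[0]:.3e} below -{PSD_TOL}"
                )
            checked.append(psd_repair(psi) if w[0] < 0 else 0.5 * (psi + psi.T))
        self.psis = checked

    @property
    def K(self) -> int:
        return len(self.psis)

    @property
    def n(self) -> int:
        return self.psis[0].shape[0]


def compute_grm(
    genotypes: GenotypeMatrix,
    method: str = "standardized",
    max_snps: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Estimate the empirical GRM from additive-coded genotypes.

    The default ``standardized`` estimator is the standardized-genotype
    cross-product: with sample allele frequency ``p_s`` at SNP s and
    ``z_is = (g_is - 2 p_s) / sqrt(2 p_s (1 - p_s))``,

        GRM[i, i'] = (1/m') sum_s z_is z_i's

    over the m' retained (polymorphic) SNPs.  ``method="correlation"``
    instead returns the rowwise Pearson correlation between samples'
    centred genotype profiles.  Missing genotypes are mean-imputed per
    SNP before standardization; monomorphic SNPs are dropped.  The
    output is symmetrized and PSD-repaired by eigenvalue clipping.

    ``max_snps`` randomly subsets the SNPs (reproducibly given ``seed``)
    before estimation, mirroring the common practice of estimating the
    GRM from a random panel of e.g. 20,000 SNPs.
    """
    if method not in ("standardized", "correlation"):
        raise ValidationError(f"unknown GRM method {method!r}")
    G = np.asarray(genotypes.values, float)
    n, m = G.shape
    if n < 2:
        raise ValidationError("GRM needs at least 2 samples")
    if max_snps is not None and max_snps < m:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(m, size=max_snps, replace=False))
        G = G[:, keep]
        m = max_snps

    # mean-impute missing values per SNP
    col_mean = np.nanmean(G, axis=0)
    nan_mask = np.isnan(G)
    if nan_mask.any():
        G = np.where(nan_mask, col_mean[None, :], G)

    p_hat = G.mean(axis=0) / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    if not poly.any():
        raise ComputationError("all SNPs are monomorphic; GRM undefined")
    G = G[:, poly]
    p_hat = p_hat[poly]

    if method == "standardized":
        Z = (G - 2 * p_hat) / np.sqrt(2 * p_hat * (1 - p_hat))
        grm = Z @ Z.T / Z.shape[1]
    else:
        C = G - G.mean(axis=1, keepdims=True)
        norms = np.sqrt((C**2).sum(axis=1))
        if (norms == 0).any():
            raise ComputationError("constant genotype row; correlation undefined")
        grm = (C @ C.T) / np.outer(norms, norms)
    return psd_repair(grm)


def family_block_matrix(family_ids) -> np.ndarray:
    """Within-family matrix of ones: Psi[i, i'] = 1 iff same family."""
    fam = np.asarray(family_ids)
    if len(fam) == 0:
        raise ValidationError("empty family label vector")
    return (fam[:, None] == fam[None, :]).astype(float)
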