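"""Simulation studies validating the whole pipeline on synthetic data.

These are first-class package functionality: each study builds a
synthetic family design with :mod:`aspuw.simulate`, pushes it through
the real GRM / null-model / test / scan code paths, and returns the
operating characteristics (empirical size, power, parameter-recovery
error, genomic-control lambda).  The test suite and the reproduction
script both call these functions rather than reimplementing the loops.

Design sizes are chosen to give statistically meaningful answers on a
single CPU in minutes; see docs/methods.md for the rationale behind
each default.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from ._seeds import derive_rng
from .model import FamilyMixedLM
from .relatedness import VarianceComponentSet, compute_grm, family_block_matrix
from .scan import genomic_lambda, run_scan
from .simulate import (
    EffectSpec,
    PedigreeSpec,
    simulate_dataset,
    simulate_genotypes,
    simulate_methylation,
    simulate_pedigree,
    simulate_phenotype,
)
from .spuw import DEFAULT_GAMMAS, GammaSet

__all__ = [
    "null_design",
    "type_one_error_study",
    "power_study",
    "reml_recovery_study",
    "score_covariance_study",
    "planted_scan_study",
]


def _ranef_factor(psis, tau):
    """Symmetric square root of sum_k tau_k Psi_k (eigenvalue clipping)."""
    cov = sum(t * p for t, p in zip(tau, psis))
    vals, vecs = np.linalg.eigh(cov)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def null_design(
    n_families: int = 200,
    family_size: int = 4,
    p_cpgs: int = 10,
    within_gene_corr: float = 0.5,
    m_snps: int = 2000,
    seed: int = 0,
):
    """Fixed design shared across phenotype replicates: pedigree,
    estimated GRM, family blocks, covariates and a correlated CpG matrix
    with heterogeneous variances."""
    ped = simulate_pedigree(PedigreeSpec(n_families, family_size, seed=seed))
    geno = simulate_genotypes(ped, m_snps, seed=seed + 1)
    grm = compute_grm(geno)
    blocks = family_block_matrix(ped.samples.family_ids)
    meth = simulate_methylation(
        ped.n, p_cpgs, within_gene_corr=within_gene_corr, seed=seed + 2
    )
    vc = VarianceComponentSet([grm, blocks], ["grm", "family"])
    return ped, meth, vc


def _replicate_pvalues(
    ped,
    meth,
    vc,
    beta,
    tau,
    sigma2,
    n_replicates,
    B,
    gammas,
    weight,
    seed,
    alpha_fixed=(1.0, 0.02, 0.5),
):
    """Simulate phenotypes, refit the null model per replicate (warm
    started), and collect per-gamma and aSPUw p-values."""
    gammas = gammas if isinstance(gammas, GammaSet) else GammaSet(tuple(gammas))
    pvals = {g: np.empty(n_replicates) for g in gammas}
    pvals["aspuw"] = np.empty(n_replicates)
    mean = ped.samples.exog @ np.asarray(alpha_fixed, float) + meth.values @ np.asarray(beta, float)
    factor = _ranef_factor(vc.psis, tau)
    warm = None
    for r in range(n_replicates):
        rng = derive_rng(seed, "study-phenotype", r)
        y = mean + rng.standard_normal(ped.n) * np.sqrt(sigma2)
        y = y + factor @ rng.standard_normal(ped.n)
        model = FamilyMixedLM(y, ped.samples.exog, vc)
        fit = model.fit(start=warm, restarts=1 if warm is not None else 3)
        warm = fit.eta
        result = fit.aspuw(meth, gammas=gammas, B=B, weight=weight, seed=seed + r)
        for g in gammas:
            pvals[g][r] = result.pvalues[g]
        pvals["aspuw"][r] = result.aspuw_pvalue
    return pvals


def type_one_error_study(
    n_families: int = 200,
    family_size: int = 4,
    p_cpgs: int = 10,
    within_gene_corr: float = 0.5,
    tau=(0.3, 0.2),
    sigma2: float = 1.0,
    n_replicates: int = 1000,
    B: int = 500,
    gammas=DEFAULT_GAMMAS,
    weight: str = "inverse_sd",
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of every SPUw(gamma) and aSPUw.

    Phenotypes are drawn from the exact null mixed model (beta = 0,
    variance components on the estimated GRM and the family blocks);
    the null model is refitted for every replicate.  Returns the
    rejection rate at ``alpha`` per test plus the raw p-values.
    """
    ped, meth, vc = null_design(
        n_families, family_size, p_cpgs, within_gene_corr, seed=seed
    )
    beta = np.zeros(meth.p)
    pvals = _replicate_pvalues(
        ped, meth, vc, beta, tau, sigma2, n_replicates, B, gammas, weight, seed
    )
    out = {
        "size": {k: float(np.mean(v < alpha)) for k, v in pvals.items()},
        "pvalues": pvals,
        "n_replicates": n_replicates,
        "alpha": alpha,
    }
    return out


def _calibrated_beta(ped, meth, vc, tau, sigma2, causal_idx, z_per_site):
    """Effect sizes giving a prescribed per-site score noncentrality.

    Under the mixed model the expected score is E U = V beta (fixed
    effects profiled out), so setting beta = c * 1 on the causal sites
    and solving mean_j (V beta)_j / sqrt(V_jj) = z_per_site over the
    causal j fixes the per-site standardized signal analytically —
    before any test is run — using the true generative covariance.
    """
    n = ped.n
    X = ped.samples.exog
    Sigma = sigma2 * np.eye(n)
    for t, psi in zip(tau, vc.psis):
        Sigma += t * psi
    c = cho_factor(Sigma, lower=True)
    G = meth.values
    SiG = cho_solve(c, G)
    SiX = cho_solve(c, X)
    A = X.T @ SiX
    V = G.T @ SiG - (SiX.T @ G).T @ np.linalg.solve(A, SiX.T @ G)
    direction = np.zeros(meth.p)
    direction[np.asarray(causal_idx)] = 1.0
    vb = V @ direction
    zs = vb[np.asarray(causal_idx)] / np.sqrt(np.diag(V)[np.asarray(causal_idx)])
    scale = z_per_site / float(np.mean(zs))
    return scale * direction


def power_study(
    scenario: str,
    n_families: int = 100,
    family_size: int = 4,
    p_cpgs: int = 20,
    within_gene_corr: float = 0.1,
    tau=(0.3, 0.2),
    sigma2: float = 1.0,
    n_replicates: int = 250,
    B: int = 500,
    gammas=DEFAULT_GAMMAS,
    weight: str = "inverse_sd",
    alpha: float = 0.05,
    z_sparse: float = 3.2,
    z_dense: float = 0.9,
    causal_index: int | None = None,
    seed: int = 0,
) -> dict:
    """Power of each SPUw(gamma) and aSPUw under a sparse (1 causal CpG)
    or dense (all CpGs causal, same sign) association pattern.

    Effect sizes are calibrated analytically to a per-site score
    noncentrality (``z_sparse`` / ``z_dense``), keeping power away from
    the floor and the ceiling so orderings between tests are visible.
    """
    if scenario not in ("sparse", "dense"):
        raise ValueError("scenario must be 'sparse' or 'dense'")
    ped, meth, vc = null_design(
        n_families, family_size, p_cpgs, within_gene_corr, seed=seed
    )
    if scenario == "sparse":
        causal = [p_cpgs // 2 if causal_index is None else causal_index]
        z = z_sparse
    else:
        causal = list(range(p_cpgs))
        z = z_dense
    beta = _calibrated_beta(ped, meth, vc, tau, sigma2, causal, z)
    pvals = _replicate_pvalues(
        ped, meth, vc, beta, tau, sigma2, n_replicates, B, gammas, weight, seed
    )
    return {
        "power": {k: float(np.mean(v < alpha)) for k, v in pvals.items()},
        "pvalues": pvals,
        "beta": beta,
        "n_replicates": n_replicates,
        "alpha": alpha,
    }


def reml_recovery_study(
    n_families: int = 250,
    family_size: int = 4,
    tau=(0.5, 0.3),
    sigma2: float = 1.0,
    n_replicates: int = 50,
    seed: int = 0,
) -> dict:
    """Parameter recovery of the REML variance-component estimates.

    Phenotypes are simulated from known (T_1, T_2, sigma^2) on the
    estimated-GRM + family-block structure and refitted; returns the
    mean estimates and their errors over replicates.
    """
    ped, meth, vc = null_design(n_families, family_size, p_cpgs=4, seed=seed)
    mean = ped.samples.exog @ np.array([1.0, 0.02, 0.5])
    factor = _ranef_factor(vc.psis, tau)
    est = np.empty((n_replicates, len(tau) + 1))
    warm = None
    for r in range(n_replicates):
        rng = derive_rng(seed, "reml-recovery", r)
        y = mean + rng.standard_normal(ped.n) * np.sqrt(sigma2)
        y = y + factor @ rng.standard_normal(ped.n)
        fit = FamilyMixedLM(y, ped.samples.exog, vc).fit(
            start=warm, restarts=1 if warm is not None else 3
        )
        warm = fit.eta
        est[r, :-1] = fit.tau
        est[r, -1] = fit.sigma2
    truth = np.append(np.asarray(tau, float), sigma2)
    mean_est = est.mean(axis=0)
    return {
        "truth": truth,
        "mean_estimates": mean_est,
        "mean_error": mean_est - truth,
        "estimates": est,
        "n_replicates": n_replicates,
    }


def score_covariance_study(
    n_families: int = 250,
    family_size: int = 4,
    p_cpgs: int = 10,
    within_gene_corr: float = 0.5,
    tau=(0.5, 0.3),
    sigma2: float = 1.0,
    n_draws: int = 10000,
    seed: int = 0,
) -> dict:
    """Empirical covariance of null score vectors versus the analytic V.

    One null model is fitted; phenotypes are then redrawn from the
    fitted Gaussian null (N(X alpha_hat, Sigma_hat)) and scored at the
    fixed fit, vectorized over draws.  Returns the analytic V, the
    Monte Carlo covariance, and the maximum entrywise relative error.
    """
    ped, meth, vc = null_design(n_families, family_size, p_cpgs, within_gene_corr, seed=seed)
    effects = EffectSpec(
        alpha=np.array([1.0, 0.02, 0.5]), beta=np.zeros(meth.p),
        tau=np.asarray(tau, float), sigma2=sigma2,
    )
    y = simulate_phenotype(ped.samples, meth, effects, vc.psis, seed=seed + 11)
    fit = FamilyMixedLM(y, ped.samples.exog, vc).fit()
    score = fit.score_vector(meth)

    rng = derive_rng(seed, "score-cov-draws")
    Sigma = fit.Sigma
    vals, vecs = np.linalg.eigh(Sigma)
    factor = vecs * np.sqrt(np.clip(vals, 0, None))
    mean = ped.samples.exog @ fit.alpha
    Y = mean[:, None] + factor @ rng.standard_normal((ped.n, n_draws))
    Udraws = fit.score_matrix(meth.values, Y)
    emp = np.cov(Udraws.T, ddof=1)
    rel = np.abs(emp - score.V) / np.abs(score.V)
    return {
        "V": score.V,
        "empirical": emp,
        "max_relative_error": float(rel.max()),
        "n_draws": n_draws,
    }


def planted_scan_study(
    n_genes: int = 3000,
    cpgs_per_gene: int = 3,
    n_families: int = 100,
    family_size: int = 4,
    planted_gene: str = "gene0042",
    planted_beta: float = 2.5,
    B: int = 1000,
    max_b: int = 100000,
    weight: str = "inverse_sd",
    seed: int = 0,
) -> dict:
    """Genome scan with one strongly associated gene among nulls.

    Returns the scan result, the rank of the planted gene by aSPUw
    p-value (1 = smallest), and the genomic-control lambda over the
    null genes.
    """
    causal = {planted_gene: np.full(cpgs_per_gene, planted_beta)}
    data = simulate_dataset(
        n_families=n_families,
        family_size=family_size,
        n_genes=n_genes,
        cpgs_per_gene=cpgs_per_gene,
        causal_genes=causal,
        seed=seed,
    )
    grm = compute_grm(data["genotypes"])
    blocks = family_block_matrix(data["samples"].family_ids)
    vc = VarianceComponentSet([grm, blocks], ["grm", "family"])
    scan = run_scan(
        data["samples"], data["methylation"], vc, data["genes"],
        B=B, max_b=max_b, weight=weight, seed=seed,
    )
    t = scan.table[scan.table["testable"]]
    p = t["aspuw_p"].to_numpy(float)
    order = np.argsort(p, kind="mergesort")
    gene_ids = t["gene_id"].to_numpy()
    rank = int(np.flatnonzero(gene_ids[order] == planted_gene)[0]) + 1
    attains_min = bool(
        t.loc[t["gene_id"] == planted_gene, "aspuw_p"].iloc[0] <= p.min()
    )
    null_p = t.loc[t["gene_id"] != planted_gene, "aspuw_p"].to_numpy(float)
    lam = genomic_lambda(null_p)
    return {
        "scan": scan,
        "planted_rank": rank,
        "planted_attains_min": attains_min,
        "lambda_null": lam,
        "n_testable": scan.n_testable,
    }
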