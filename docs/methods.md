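# Methods

## The problem

Epigenome-wide association studies usually test each CpG site
separately, which costs power twice: a genome-wide multiplicity burden
per site, and no pooling of information across the several CpGs of a
gene that may be jointly associated (possibly in different directions).
`aspuw` implements a gene-level alternative for *family* methylation
data: the weighted sum of powered score (SPUw) family of tests and
their adaptive minimum-p combination (aSPUw), built on the score vector
of a linear mixed model that accounts for relatedness.

## Null model

For n related individuals with phenotype y, covariates X (intercept
included) and K prespecified PSD correlation structures Psi_k,

    y = X a + u + e,    u ~ N(0, sum_k T_k Psi_k),    e ~ N(0, sigma^2 I).

The structures used genome-wide are the empirical GRM (standardized
genotype cross-product over polymorphic SNPs, mean-imputed missing
calls, eigenvalue-clipped to PSD) and a within-family block matrix of
ones (shared environment).  A residual term sigma^2 I is always
included in addition to the listed Psi_k; the model is degenerate
without it.  Only the identity link (Gaussian phenotype) is supported:
the score machinery is derived for the linear mixed model, and binary
traits are out of scope.

Fitting is by REML.  The residual variance is profiled out
analytically, so the search runs over the K variance ratios
phi_k = T_k / sigma^2 on the log scale (unconstrained; the box
[-25, 12] in log phi only prevents overflow).  The optimizer is
L-BFGS-B with the exact analytic gradient of the profiled objective,
run from up to three dispersed starting points (log phi = log 0.5,
log 0.05, log 2); a Nelder–Mead fallback is triggered only when the
gradient at the quasi-Newton solution is still above tolerance away
from the boundary.  Convergence is declared when the max-norm of the
log-scale gradient is below 1e-6; a gradient above 1e-2 raises an
error carrying the optimization trace.  With Psi = I the total
variance is identified only as sigma^2 + T; the profiled objective is
flat along that ridge and the fitted total covariance is still
correct (this aliasing is exercised in the tests).

Repeated fits inside simulation studies warm-start from the previous
optimum with a single start; this changes nothing statistically, only
the wall-clock cost.

## Score statistics

With the REML plug-ins (T_hat, sigma2_hat) and Sigma_hat the fitted
total covariance, a gene's n x p CpG matrix G yields

    U = G' Sigma_hat^-1 (y - X a_hat),
    V = G' P_hat G,
    P_hat = Sigma_hat^-1 - Sigma_hat^-1 X (X' Sigma_hat^-1 X)^-1 X' Sigma_hat^-1,

the standard Gaussian score and its null covariance with fixed effects
profiled out.  No small-sample correction for estimating (T, sigma^2)
is applied — the usual plug-in score-test practice.  CpGs with zero
sample variance (exactly constant columns) are dropped with a logged
warning; a gene with no remaining CpGs is reported untestable rather
than given p = 1.  The null model is fitted once per phenotype;
per-gene work is only score extraction, which is what makes a
many-thousand-gene scan cheap.

## SPUw and aSPUw

For weights w and power gamma,

    T_SPUw(gamma) = sum_j (w_j U_j)^gamma,

with w_j = 1/sd(G_ij) (sample SD, ddof 1) or w_j = 1, in which case the
test is the unweighted SPU.  gamma = 1 is the (weighted) burden-style
sum test, gamma = 2 with unit weights is exactly U'U, the linear-kernel
SKAT statistic.  The gamma = infinity statistic is taken as
max_j |w_j U_j|, the standard limiting form of the family (the limit
statement "SPUw(inf) is the minimum-p test" is exact only when the
weights are reciprocal score standard deviations, not reciprocal
methylation SDs; we implement the inverse-methylation-SD weights as
defined and note the discrepancy).

P-values come from a single layer of Monte Carlo: B null scores
U^(b) ~ N(0, V), drawn through a symmetric eigenfactorization of V with
negative eigenvalues clipped at zero, shared across all gamma (sharing
is required for the joint min-p null).  Two-sided comparisons use
absolute values, since odd gammas give signed statistics:

    P_SPUw(gamma) = [1 + #{b : |T^(b)| >= |T|}] / (B + 1).

Ties count toward significance (conservative).  The adaptive statistic
is T_aSPUw = min_gamma P_SPUw(gamma); each replicate b1 gets its own
per-gamma leave-one-out p-values #{b != b1 : |T^(b)| >= |T^(b1)|}/B,
minimized over gamma, and

    P_aSPUw = [1 + #{b1 : min_gamma p^(b1) <= T_aSPUw}] / (B + 1).

All p-values therefore lie in [1/(B+1), 1]; the implementation never
reports 0.  Note the min-p adjustment has a floor slightly above
1/(B+1): for each gamma at least one replicate attains a leave-one-out
p of exactly 0, so a handful of replicates always tie at the bottom.

Defaults: Gamma = {1, ..., 6, inf} (small gammas for dense signals,
large and inf for sparse ones), B = 1000.  An optional staged scheme
escalates B tenfold (up to `max_b`) whenever the smallest p-value is
below 5/B, so genome-wide scans resolve small p-values without paying
the maximal B for every gene.  Per-gene seeds are derived from
(master seed, CRC-32 of gene_id), making scan output independent of
gene order and of the Python hash seed.

## Genome scan

CpGs map to genes by position against BED intervals, 0-based half-open
[start, end), gene "region" semantics being the annotation provider's
responsibility; a CpG in two overlapping genes contributes to both;
genes with no CpGs are retained and flagged untestable.  Multiple
testing uses Bonferroni over testable genes (alpha / #testable).
Calibration is summarized by the genomic-control lambda: the median of
qchisq(1 - p, df = 1) over genes divided by the chi-square-1 median
(about 0.4549).  Per-gene failures are recorded in the result row and
never abort a scan.

## Synthetic data generator

The generator exists so the whole pipeline is testable end to end with
no external data.

* **Pedigrees** — nuclear families (two unrelated founders plus
  children); relatedness 0.5 for parent–offspring and full siblings,
  zero otherwise.  Covariates are an intercept, a uniform age-like
  variable on [20, 70] and a Bernoulli(1/2) sex-like variable,
  matching the usual age/sex adjustment set.
* **Genotypes** — gene-dropping: founders draw two Bernoulli(MAF)
  alleles per SNP (Hardy–Weinberg), children inherit one uniformly
  chosen allele from each parent per SNP, so realized relatedness
  matches the pedigree in expectation and the estimated GRM is a
  realistic noisy version of it.
* **Methylation** — latent Gaussians with exchangeable correlation rho
  *within a gene* (a per-sample shared factor per gene; genes are
  independent), mapped through expit(a_j z).  The scale a_j is
  calibrated by Gauss–Hermite quadrature so the population SD of CpG j
  equals the requested `variance_profile[j]` (targets must be in
  (0, 0.5); the default profile spreads SDs over [0.02, 0.2]).  Values
  are centred at 0.5 and always lie in (0, 1).  Heterogeneous
  variances are essential: they are the entire difference between
  weighted and unweighted tests.
* **Phenotypes** — y = X a + G b + u + e with u drawn from
  N(0, sum_k T_k Psi_k); b = 0 gives an exact null generator.

Not emulated: 450K probe chemistry and measurement error, batch and
cell-type composition effects, normalization artifacts, genome-scale
LD, CpG mean profiles other than 0.5, parental-genotype-linked
methylation.  Passing tests therefore demonstrate the statistical
machinery under a clean mixed-model world, not robustness to array
artifacts.

## Validation studies and their sizes

`aspuw.studies` packages the simulation studies; the test suite and
`scripts/acceptance.py` call these functions.  Sizes were chosen once
to give informative answers in minutes on one CPU:

* **Type-I error** — 200 nuclear families of 4 (n = 800), 10 CpGs with
  latent rho 0.5 and heterogeneous variances, T = (0.3, 0.2) on
  (estimated GRM, family blocks), sigma^2 = 1; 1000 phenotype
  replicates, each with a full REML refit; B = 500.  At alpha = 0.05
  the 99% binomial band for 1000 replicates is [0.032, 0.068].
* **Power / adaptivity** — 100 families of 4, 20 CpGs, latent rho 0.1
  (kept low so a sparse signal does not leak into the sum test through
  within-gene correlation), 250 replicates, B = 500.  Effect sizes are
  calibrated analytically through E U = V beta to a per-site
  standardized score signal (3.2 for the single causal site in the
  sparse scenario, 0.9 per site in the dense one), placing every test's
  power away from floor and ceiling so orderings are visible.
* **REML recovery** — (T1, T2, sigma^2) = (0.5, 0.3, 1.0), n = 1000,
  50 replicates; mean estimates checked within +/- 0.15.
* **Score covariance** — one fixed fit, 10,000 phenotype redraws from
  the fitted null, vectorized scoring; with 10,000 draws the Monte
  Carlo noise on each covariance entry is about 2.5% relative, so the
  10% acceptance band is a ~4-sigma check (2000 draws would make the
  same band a coin flip across 55 entries, which is why the larger
  draw count is the default).
* **Planted scan** — 3000 genes of 3 CpGs on 100 families of 4, one
  gene with a strong dense effect (beta = 2.5 per CpG), B = 1000
  escalating to 1e5.  The genomic-control lambda over the 2999 null
  genes has Monte Carlo SD about 0.04 at this gene count, so the
  [0.9, 1.1] band is a comfortable check; with only a few hundred null
  genes the same band would fail on noise alone.

## Known limitations

* Gaussian phenotypes only; no logistic/Poisson mixed models.
* Monte Carlo p-values only; no asymptotic approximation for the
  adaptive combination, so the smallest resolvable p-value is
  1/(B+1) and genome-wide hits need the staged-B escalation.
* V is the plug-in score covariance; no correction for variance
  component estimation error (standard practice, slightly optimistic
  in very small samples).
* No methylation normalization of any kind is applied or provided.
* The combination of weighted and unweighted tests into a single
  omnibus is not implemented; run the two modes separately.
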