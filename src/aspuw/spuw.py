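"""Sum of powered score tests and their adaptive combination.

For a gene with score vector U and null covariance V, the weighted sum
of powered score statistic with power gamma is

    T_SPUw(gamma) = sum_j (w_j U_j)^gamma,

with weights w_j = 1 / sd(G_ij) (inverse methylation standard
deviation) or w_j = 1 (reducing to the unweighted SPU test).  The
limiting gamma = infinity statistic is max_j |w_j U_j|.  Small gamma
pool dense signals; large gamma concentrate on the strongest site, so a
single gamma is only powerful for the association pattern it happens to
match.  The adaptive test takes

    T_aSPUw = min_{gamma in Gamma} P_SPUw(gamma)

and corrects for having searched over Gamma with a single layer of
Monte Carlo: B null score vectors U^(b) ~ N(0, V) are shared across all
gamma, each observed p-value uses the two-sided counting estimator

    P_SPUw(gamma) = [1 + sum_b I(|T^(b)| >= |T|)] / (B + 1),

and each replicate's own minimum p-value over Gamma (computed
leave-one-out against the other B - 1 replicates) yields

    P_aSPUw = [1 + sum_b I(T_aSPUw^(b) <= T_aSPUw)] / (B + 1).

All reported p-values therefore lie in [1/(B+1), 1] and can never be 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_rng
from .exceptions import ComputationError, ValidationError
from .io import MethylationMatrix

__all__ = [
    "DEFAULT_GAMMAS",
    "WeightVector",
    "GammaSet",
    "TestResult",
    "compute_weights",
    "spuw_statistic",
    "simulate_null_scores",
    "spuw_pvalues",
    "aspuw_test",
]

DEFAULT_GAMMAS = (1, 2, 3, 4, 5, 6, math.inf)


@dataclass(frozen=True)
class GammaSet:
    """Ordered set of candidate powers; ``math.inf`` is allowed."""

    gammas: tuple = DEFAULT_GAMMAS

    def __post_init__(self):
        gs = tuple(self.gammas)
        if not gs:
            raise ValidationError("Gamma set must be nonempty")
        for g in gs:
            if g != math.inf and (int(g) != g or g < 1):
                raise ValidationError(f"gamma must be a positive integer or inf: {g}")
        if len(set(gs)) != len(gs):
            raise ValidationError("duplicate gamma values")
        object.__setattr__(self, "gammas", gs)

    def __iter__(self):
        return iter(self.gammas)

    def __len__(self):
        return len(self.gammas)

    @staticmethod
    def parse(text: str) -> "GammaSet":
        """Parse e.g. ``"1,2,3,inf"`` or ``"1..6,inf"``."""
        out = []
        for tok in str(text).split(","):
            tok = tok.strip()
            if tok.lower() in ("inf", "infinity"):
                out.append(math.inf)
            elif ".." in tok:
                lo, hi = tok.split("..")
                out.extend(range(int(lo), int(hi) + 1))
            else:
                out.append(int(tok))
        return GammaSet(tuple(out))


@dataclass
class WeightVector:
    """Per-CpG weights w_j, strictly positive and finite."""

    omega: np.ndarray
    mode: str

    def __post_init__(self):
        self.omega = np.atleast_1d(np.asarray(self.omega, float))
        if self.mode not in ("inverse_sd", "constant"):
            raise ValidationError(f"unknown weight mode {self.mode!r}")
        if not np.all(np.isfinite(self.omega)) or (self.omega <= 0).any():
            raise ComputationError("weights must be strictly positive and finite")


@dataclass
class TestResult:
    """Per-gamma SPUw statistics and p-values plus the adaptive p-value."""

    gammas: GammaSet
    statistics: dict
    pvalues: dict
    aspuw_pvalue: float
    B: int
    seed: int | None = None
    weight_mode: str | None = None
    cpg_ids: np.ndarray | None = None
    untestable: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def min_gamma_pvalue(self) -> float:
        return min(self.pvalues.values())

    def to_row(self) -> dict:
        row = {}
        for g in self.gammas:
            key = "inf" if g == math.inf else str(int(g))
            row[f"spuw_{key}_stat"] = self.statistics.get(g, np.nan)
            row[f"spuw_{key}_p"] = self.pvalues.get(g, np.nan)
        row["aspuw_p"] = self.aspuw_pvalue
        row["B"] = self.B
        return row


def compute_weights(G, mode: str = "inverse_sd") -> WeightVector:
    """Weights from a CpG matrix: inverse sample SD (ddof = 1) or all 1."""
    if isinstance(G, MethylationMatrix):
        G = G.values
    G = np.atleast_2d(np.asarray(G, float))
    p = G.shape[1]
    if mode == "constant":
        return WeightVector(np.ones(p), "constant")
    if mode != "inverse_sd":
        raise ValidationError(f"unknown weight mode {mode!r}")
    sd = G.std(axis=0, ddof=1)
    if (sd <= 0).any() or not np.all(np.isfinite(sd)):
        raise ComputationError(
            "zero-variance CpG reached the weight computation; drop it upstream"
        )
    return WeightVector(1.0 / sd, "inverse_sd")


def spuw_statistic(U: np.ndarray, omega, gamma) -> float:
    """T_SPUw(gamma) = sum_j (w_j U_j)^gamma; gamma = inf -> max_j |w_j U_j|."""
    U = np.atleast_1d(np.asarray(U, float))
    w = omega.omega if isinstance(omega, WeightVector) else np.asarray(omega, float)
    wU = w * U
    if gamma == math.inf:
        return float(np.max(np.abs(wU)))
    g = int(gamma)
    if g < 1:
        raise ValidationError("gamma must be >= 1")
    return float(np.sum(wU**g))


def simulate_null_scores(V: np.ndarray, B: int, seed: int = 0) -> np.ndarray:
    """B draws of U ~ N(0, V) via a symmetric eigenfactorization.

    Negative eigenvalues (within the PSD tolerance) are clipped at 0, so
    rank-deficient V is handled exactly; the draws are reproducible
    given the seed.
    """
    V = np.atleast_2d(np.asarray(V, float))
    if V.shape[0] != V.shape[1] or not np.allclose(V, V.T, atol=1e-8):
        raise ValidationError("V must be square and symmetric")
    if B < 1:
        raise ValidationError("B must be >= 1")
    vals, vecs = np.linalg.eigh(V)
    vals = np.clip(vals, 0.0, None)
    factor = vecs * np.sqrt(vals)
    rng = derive_rng(seed, "null-scores")
    return rng.standard_normal((B, V.shape[0])) @ factor.T


def _null_statistics(draws: np.ndarray, omega: np.ndarray, gammas) -> dict:
    wD = draws * omega
    out = {}
    for g in gammas:
        if g == math.inf:
            out[g] = np.max(np.abs(wD), axis=1)
        else:
            out[g] = np.sum(wD ** int(g), axis=1)
    return out


def spuw_pvalues(
    U: np.ndarray,
    V: np.ndarray,
    omega: WeightVector,
    gammas: GammaSet | tuple = DEFAULT_GAMMAS,
    B: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Monte Carlo p-values for every SPUw(gamma) and for aSPUw.

    The same B null draws are shared across all gamma — required for
    the joint min-p null distribution.  Per-gamma p-values use the
    two-sided counting formula with the +1/(B+1) correction; the
    adaptive p-value compares the observed minimum p-value against each
    replicate's own leave-one-out minimum.  Indicators use >= / <=, so
    ties count toward significance (conservative).
    """
    gammas = gammas if isinstance(gammas, GammaSet) else GammaSet(tuple(gammas))
    omega = omega if isinstance(omega, WeightVector) else WeightVector(omega, "constant")
    U = np.atleast_1d(np.asarray(U, float))
    if omega.omega.shape != U.shape:
        raise ValidationError("weight / score length mismatch")
    if B < len(gammas):
        warnings.warn(
            f"B = {B} below |Gamma| = {len(gammas)}: aSPUw p-value resolution is coarse",
            stacklevel=2,
        )
    draws = simulate_null_scores(V, B, seed=seed)
    return _pvalues_from_draws(U, draws, omega, gammas, seed=seed)


def _pvalues_from_draws(U, draws, omega, gammas, seed=None) -> TestResult:
    """Counting-formula p-values given precomputed null score draws."""
    B = draws.shape[0]
    w = omega.omega
    obs = {g: spuw_statistic(U, w, g) for g in gammas}
    null = _null_statistics(draws, w, gammas)

    pvals = {}
    loo_min = np.full(B, np.inf)
    for g in gammas:
        a_null = np.abs(null[g])
        a_obs = abs(obs[g])
        pvals[g] = (1.0 + int(np.count_nonzero(a_null >= a_obs))) / (B + 1.0)
        # leave-one-out p-values for every replicate, vectorized:
        # count over ALL b of |T^(b)| >= |T^(b1)| includes b1 itself once
        order = np.sort(a_null)
        count_ge = B - np.searchsorted(order, a_null, side="left")
        p_b = (count_ge - 1) / B
        loo_min = np.minimum(loo_min, p_b)

    t_aspuw = min(pvals.values())
    p_aspuw = (1.0 + int(np.count_nonzero(loo_min <= t_aspuw))) / (B + 1.0)
    return TestResult(
        gammas=gammas,
        statistics=obs,
        pvalues=pvals,
        aspuw_pvalue=p_aspuw,
        B=B,
        seed=seed,
        weight_mode=omega.mode,
    )


def aspuw_test(
    fit,
    G,
    cpg_ids=None,
    gammas: GammaSet | tuple | None = None,
    B: int = 1000,
    weight: str = "inverse_sd",
    seed: int = 0,
    max_b: int | None = None,
) -> TestResult:
    """Full gene-level test: weights -> scores -> Monte Carlo p-values.

    ``fit`` is a :class:`~aspuw.model.FamilyMixedLMResults`.  When
    ``max_b`` exceeds ``B``, the Monte Carlo size escalates tenfold
    (up to ``max_b``) whenever the smallest p-value is below 5/B, so a
    genome-wide scan resolves small p-values without paying the maximal
    B everywhere.
    """
    gammas = (
        GammaSet(tuple(gammas)) if gammas is not None and not isinstance(gammas, GammaSet)
        else (gammas or GammaSet())
    )
    if isinstance(G, MethylationMatrix):
        cpg_ids = G.cpg_ids
        G_vals = G.values
    else:
        G_vals = np.atleast_2d(np.asarray(G, float))
    score = fit.score_vector(G_vals, cpg_ids=cpg_ids)
    if score.p == 0:
        return TestResult(
            gammas=gammas, statistics={}, pvalues={}, aspuw_pvalue=np.nan,
            B=0, seed=seed, weight_mode=weight, cpg_ids=score.cpg_ids,
            untestable=True,
        )
    # weights come from the retained CpGs only, in score order
    if cpg_ids is not None:
        keep = np.isin(np.asarray(cpg_ids), score.cpg_ids)
        G_kept = G_vals[:, keep]
    else:
        G_kept = G_vals
    omega = compute_weights(G_kept, mode=weight)

    b_now = int(B)
    while True:
        result = spuw_pvalues(score.U, score.V, omega, gammas, B=b_now, seed=seed)
        min_p = min(result.min_gamma_pvalue, result.aspuw_pvalue)
        if max_b is None or b_now >= max_b or min_p >= 5.0 / b_now:
            break
        b_now = min(b_now * 10, int(max_b))
    result.cpg_ids = score.cpg_ids
    result.weight_mode = weight
    result.extra["n_cpgs"] = score.p
    return result
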