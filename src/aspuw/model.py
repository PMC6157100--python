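"""The Gaussian null mixed model and its score statistics.

The model for a quantitative phenotype on n related individuals is

    y = X a + u + e,   u ~ N(0, sum_k T_k Psi_k),   e ~ iid N(0, sigma^2 I),

with X the fixed covariates (intercept included) and the Psi_k
prespecified PSD correlation structures (empirical GRM, within-family
blocks, ...).  A residual variance sigma^2 I is always present in the
total covariance Sigma = sigma^2 I + sum_k T_k Psi_k in addition to the
listed components; the model is degenerate without it.

``FamilyMixedLM.fit`` maximizes the REML log-likelihood.  The residual
variance is profiled out analytically, so the numerical search runs
over the K variance ratios phi_k = T_k / sigma^2 on the log scale
(unconstrained); a quasi-Newton polish with the analytic gradient
follows a Nelder–Mead sweep from dispersed starting points.

From the fitted null model, ``score_vector`` extracts for a gene's CpG
matrix G the score vector and its null covariance with fixed effects
profiled out:

    U = G' Sigma^-1 (y - X a_hat),      V = G' P G,
    P = Sigma^-1 - Sigma^-1 X (X' Sigma^-1 X)^-1 X' Sigma^-1.

Under the null, U ~ N(0, V) asymptotically; these two objects are the
only inputs the SPUw/aSPUw tests need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, lapack
from scipy.optimize import minimize

from .exceptions import FitError, ValidationError
from .io import MethylationMatrix, SampleFrame
from .relatedness import VarianceComponentSet

__all__ = ["FamilyMixedLM", "FamilyMixedLMResults", "ScoreVector", "fit_null_lmm"]

logger = logging.getLogger(__name__)

_LOG_PHI_BOUNDS = (-25.0, 12.0)


@dataclass
class ScoreVector:
    """Score vector U and its null covariance V for one gene's CpGs."""

    U: np.ndarray
    V: np.ndarray
    cpg_ids: np.ndarray

    def __post_init__(self):
        self.U = np.atleast_1d(np.asarray(self.U, float))
        self.V = np.atleast_2d(np.asarray(self.V, float))
        p = self.U.shape[0]
        if self.V.shape != (p, p):
            raise ValidationError("V must be p x p for a p-vector U")
        if not np.allclose(self.V, self.V.T, atol=1e-8):
            raise ValidationError("V must be symmetric")
        wmin = np.linalg.eigvalsh(self.V)[0] if p else 0.0
        if p and wmin < -1e-8 * max(1.0, np.abs(self.V).max()):
            raise ValidationError(f"V has eigenvalue {wmin:.3e} below tolerance")

    @property
    def p(self) -> int:
        return self.U.shape[0]


class FamilyMixedLM:
    """Gaussian linear mixed model with prespecified covariance structures.

    Parameters
    ----------
    endog
        Phenotype vector y (n,).
    exog
        Fixed-effect design matrix X (n, q), full column rank, intercept
        included by the caller.
    variance_components
        ``VarianceComponentSet`` with the K matrices Psi_k, or None for
        an ordinary (independent-errors) linear model.
    """

    def __init__(self, endog, exog, variance_components: VarianceComponentSet | None):
        self.endog = np.asarray(endog, float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, float))
        self.vc = variance_components
        n, q = self.exog.shape
        if self.endog.shape != (n,):
            raise ValidationError("endog/exog length mismatch")
        if n <= q:
            raise ValidationError("need n > q observations")
        if np.linalg.matrix_rank(self.exog) < q:
            raise ValidationError("exog is rank deficient")
        if self.vc is not None and self.vc.n != n:
            raise ValidationError("Psi dimension does not match sample count")
        self.n, self.q = n, q

    @classmethod
    def from_frames(
        cls,
        samples: SampleFrame,
        variance_components: VarianceComponentSet | None,
        covariates: list[str] | None = None,
    ) -> "FamilyMixedLM":
        if covariates is not None:
            samples = SampleFrame(samples.data, list(covariates))
        return cls(samples.endog, samples.exog, variance_components)

    # -- profiled REML machinery -----------------------------------------

    def _eval(self, eta: np.ndarray, want_grad: bool = False):
        """Profiled negative REML log-likelihood (and gradient) at
        eta = log phi.  Constants independent of the parameters are
        dropped."""
        y, X, n, q = self.endog, self.exog, self.n, self.q
        phi = np.exp(eta)
        R = np.eye(n)
        for ph, psi in zip(phi, self.vc.psis):
            R += ph * psi
        try:
            c = cho_factor(R, lower=True)
        except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
            raise FitError(f"covariance not positive definite at phi={phi}") from err
        logdet_R = 2.0 * np.log(np.diag(c[0])).sum()
        Riy = cho_solve(c, y)
        RiX = cho_solve(c, X)
        A = X.T @ RiX
        cA = cho_factor(A, lower=True)
        logdet_A = 2.0 * np.log(np.diag(cA[0])).sum()
        alpha = cho_solve(cA, X.T @ Riy)
        Py = Riy - RiX @ alpha
        Q = float(y @ Py)
        f = 0.5 * ((n - q) * np.log(Q) + logdet_R + logdet_A)
        if not want_grad:
            return f, (c, cA, RiX, Riy, alpha, Py, Q, R)
        inv_tri, info = lapack.dpotri(c[0], lower=True)
        if info != 0:  # pragma: no cover - defensive
            raise FitError(f"dpotri failed with info={info}")
        Rinv = np.tril(inv_tri) + np.tril(inv_tri, -1).T
        grad = np.empty(len(phi))
        for k, psi in enumerate(self.vc.psis):
            tr_Ri = float(np.sum(Rinv * psi))
            M = RiX.T @ (psi @ RiX)  # X' R^-1 Psi R^-1 X
            tr_proj = float(np.trace(cho_solve(cA, M)))
            quad = float(Py @ (psi @ Py))
            dfdphi = 0.5 * (tr_Ri - tr_proj - (n - q) * quad / Q)
            grad[k] = dfdphi * phi[k]  # chain rule to the log scale
        return f, grad, (c, cA, RiX, Riy, alpha, Py, Q, R)

    def _fit_ols(self) -> "FamilyMixedLMResults":
        y, X, n, q = self.endog, self.exog, self.n, self.q
        alpha, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ alpha
        sigma2 = float(resid @ resid) / (n - q)
        return FamilyMixedLMResults(
            model=self,
            alpha=alpha,
            tau=np.zeros(0),
            sigma2=sigma2,
            eta=np.zeros(0),
            converged=True,
            grad_norm=0.0,
            objective=0.5 * (n - q) * np.log(resid @ resid),
            n_restarts=0,
        )

    def fit(
        self,
        start: np.ndarray | None = None,
        restarts: int = 3,
        maxiter: int = 500,
        grad_tol: float = 1e-6,
        polish: bool = True,
    ) -> "FamilyMixedLMResults":
        """Fit by REML.

        ``start`` (log variance ratios) seeds the first search; with
        ``restarts`` > 1 additional dispersed starting points are used
        and the best objective wins.  ``polish`` runs an L-BFGS-B pass
        with the analytic gradient after the derivative-free sweep.
        """
        if self.vc is None:
            return self._fit_ols()
        K = self.vc.K
        starts = []
        if start is not None:
            starts.append(np.asarray(start, float))
        for v in (np.log(0.5), np.log(0.05), np.log(2.0)):
            starts.append(np.full(K, v))
        starts = starts[: max(restarts, 1)]

        trace = []
        eta, fun = None, np.inf
        for x0 in starts:
            res = minimize(
                lambda e: self._eval(e, want_grad=True)[:2],
                np.clip(x0, *_LOG_PHI_BOUNDS),
                jac=True,
                method="L-BFGS-B",
                bounds=[_LOG_PHI_BOUNDS] * K,
                options={"maxiter": maxiter, "gtol": grad_tol / 2, "ftol": 1e-14},
            )
            trace.append((res.x.copy(), float(res.fun)))
            if res.fun < fun:
                eta, fun = np.clip(res.x, *_LOG_PHI_BOUNDS), float(res.fun)
        f, grad, cache = self._eval(eta, want_grad=True)
        grad_norm = float(np.max(np.abs(grad)))
        at_bound = np.any(np.isclose(eta, _LOG_PHI_BOUNDS, atol=1e-6))
        if polish and grad_norm > grad_tol and not at_bound:
            # derivative-free fallback for flat or awkwardly scaled
            # objectives where the quasi-Newton line search stalls
            res = minimize(
                lambda e: self._eval(e)[0],
                eta,
                method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-12},
            )
            trace.append((res.x.copy(), float(res.fun)))
            if res.fun <= fun:
                eta, fun = np.clip(res.x, *_LOG_PHI_BOUNDS), float(res.fun)
                f, grad, cache = self._eval(eta, want_grad=True)
                grad_norm = float(np.max(np.abs(grad)))
        # at the box boundary (phi ~ 0) the log-scale gradient vanishes;
        # flag non-convergence only for genuinely unresolved interior optima
        converged = grad_norm < max(grad_tol, 1e-6)
        if not converged and grad_norm > 1e-2:
            raise FitError(
                f"REML did not converge: |grad|={grad_norm:.2e}", trace=trace
            )
        c, cA, RiX, Riy, alpha, Py, Q, R = cache
        sigma2 = Q / (self.n - self.q)
        phi = np.exp(eta)
        tau = phi * sigma2
        self.vc.tau = tau
        self.vc.sigma2 = float(sigma2)
        return FamilyMixedLMResults(
            model=self,
            alpha=alpha,
            tau=tau,
            sigma2=float(sigma2),
            eta=eta,
            converged=converged,
            grad_norm=grad_norm,
            objective=float(f),
            n_restarts=len(starts),
            _cache=(c, cA, RiX, Py, R),
        )


class FamilyMixedLMResults:
    """REML estimates and cached GLS quantities from ``FamilyMixedLM.fit``.

    Attributes
    ----------
    alpha : fixed-effect estimates (GLS at the REML optimum)
    tau : fitted variance components T_k (same order as the Psi_k)
    sigma2 : residual variance
    converged : True when the log-scale gradient norm met tolerance
    """

    def __init__(
        self,
        model,
        alpha,
        tau,
        sigma2,
        eta,
        converged,
        grad_norm,
        objective,
        n_restarts,
        _cache=None,
    ):
        self.model = model
        self.alpha = np.asarray(alpha, float)
        self.tau = np.asarray(tau, float)
        self.sigma2 = float(sigma2)
        self.eta = np.asarray(eta, float)
        self.converged = bool(converged)
        self.grad_norm = float(grad_norm)
        self.objective = float(objective)
        self.n_restarts = int(n_restarts)
        if _cache is None:
            n = model.n
            R = np.eye(n)
            if model.vc is not None:
                for t, psi in zip(self.tau, model.vc.psis):
                    R += (t / self.sigma2) * psi
            c = cho_factor(R, lower=True)
            RiX = cho_solve(c, model.exog)
            A = model.exog.T @ RiX
            cA = cho_factor(A, lower=True)
            Riy = cho_solve(c, model.endog)
            Py = Riy - RiX @ cho_solve(cA, model.exog.T @ Riy)
            _cache = (c, cA, RiX, Py, R)
        self._chol_R, self._chol_A, self._RiX, self._Py, self._R = _cache

    # -- fitted covariance ------------------------------------------------
    @property
    def Sigma(self) -> np.ndarray:
        """Total fitted covariance sigma^2 I + sum_k T_k Psi_k."""
        return self.sigma2 * self._R

    @property
    def resid(self) -> np.ndarray:
        """GLS residual y - X alpha_hat."""
        return self.model.endog - self.model.exog @ self.alpha

    def cov_params(self) -> np.ndarray:
        """Covariance of the fixed-effect estimates, (X' Sigma^-1 X)^-1."""
        q = self.model.q
        return self.sigma2 * cho_solve(self._chol_A, np.eye(q))

    # -- score machinery --------------------------------------------------
    def score_vector(self, G, cpg_ids=None) -> ScoreVector:
        """Score U and covariance V for a CpG matrix G (n x p).

        CpGs with zero sample variance are dropped with a logged
        warning before computation.  An empty result (p = 0 after
        filtering) signals an untestable gene to the caller.
        """
        if isinstance(G, MethylationMatrix):
            cpg_ids = G.cpg_ids
            G = G.values
        G = np.atleast_2d(np.asarray(G, float))
        if G.shape[0] != self.model.n:
            raise ValidationError("G rows do not match sample count")
        p = G.shape[1]
        if cpg_ids is None:
            cpg_ids = np.array([f"cpg{j}" for j in range(p)])
        cpg_ids = np.asarray(cpg_ids)
        if G.shape[0] > 1:
            # a column is zero-variance iff it is constant; ptp avoids
            # spurious 1e-33 variances from rounding in the mean
            keep = (G.max(axis=0) - G.min(axis=0)) > 0
        else:
            keep = np.zeros(p, dtype=bool)
        if not keep.all():
            dropped = cpg_ids[~keep]
            logger.warning(
                "dropping %d zero-variance CpG(s): %s",
                len(dropped),
                ", ".join(map(str, dropped[:5])),
            )
            G = G[:, keep]
            cpg_ids = cpg_ids[keep]
        if G.shape[1] == 0:
            return ScoreVector(np.zeros(0), np.zeros((0, 0)), cpg_ids)
        U = (G.T @ self._Py) / self.sigma2
        RiG = cho_solve(self._chol_R, G)
        B = self._RiX.T @ G  # X' R^-1 G
        V = (G.T @ RiG - B.T @ cho_solve(self._chol_A, B)) / self.sigma2
        V = 0.5 * (V + V.T)
        return ScoreVector(U, V, cpg_ids)

    def score_matrix(self, G: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Score vectors for many phenotype vectors at this fixed fit.

        ``Y`` is (n, N); returns (N, p) with row r the score U computed
        from phenotype Y[:, r] (the GLS residual is recomputed per
        column; the variance parameters stay plugged in).
        """
        G = np.atleast_2d(np.asarray(G, float))
        Y = np.atleast_2d(np.asarray(Y, float))
        RiY = cho_solve(self._chol_R, Y)
        XtRiY = self.model.exog.T @ RiY
        PY = RiY - self._RiX @ cho_solve(self._chol_A, XtRiY)
        return (G.T @ PY).T / self.sigma2

    def aspuw(
        self,
        G,
        cpg_ids=None,
        gammas=None,
        B: int = 1000,
        weight: str = "inverse_sd",
        seed: int = 0,
        max_b: int | None = None,
    ):
        """Run the aSPUw test for one gene's CpG matrix; see
        :func:`aspuw.spuw.aspuw_test`."""
        from .spuw import aspuw_test

        return aspuw_test(
            self, G, cpg_ids=cpg_ids, gammas=gammas, B=B, weight=weight,
            seed=seed, max_b=max_b,
        )

    def summary(self) -> str:
        """Plain-text summary of the null-model fit."""
        lines = [
            "Family mixed LM (REML), identity link",
            f"  n = {self.model.n}, q = {self.model.q}",
            f"  converged: {self.converged} (|grad| = {self.grad_norm:.2e})",
            "",
            "Fixed effects (GLS)     estimate      std err",
        ]
        se = np.sqrt(np.diag(self.cov_params()))
        for j, (a, s) in enumerate(zip(self.alpha, se)):
            lines.append(f"  x{j:<20d} {a:12.5f} {s:12.5f}")
        lines.append("")
        lines.append("Variance components")
        labels = self.model.vc.labels if self.model.vc is not None else []
        for lab, t in zip(labels, self.tau):
            lines.append(f"  T[{lab:<18s}] {t:12.5f}")
        lines.append(f"  sigma2{'':<16s} {self.sigma2:12.5f}")
        return "\n".join(lines)


def fit_null_lmm(y, X, variance_components: VarianceComponentSet | None, **kwargs):
    """Functional wrapper: build and fit the null mixed model."""
    return FamilyMixedLM(y, X, variance_components).fit(**kwargs)
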