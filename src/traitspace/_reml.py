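"""Profiled REML for linear mixed models with independent variance components.

Model::

    y = X beta + sum_c Z_c u_c + e,   u_c ~ N(0, s2_c I),   e ~ N(0, s2_e I)

with mutually independent components (no covariances between random
effects).  This covers crossed random intercepts (perceiver, trait pair),
a perceiver-by-pair interaction, and an independent random slope, which is
exactly the structure needed here: components may be crossed, not nested,
so the likelihood cannot be factored by cluster.

The implementation profiles out ``beta`` and ``s2_e`` and minimizes the
REML deviance over the per-component standard-deviation ratios
``s_c = sqrt(s2_c / s2_e)`` using the penalized least-squares / Cholesky
identity (the same profiling used by lme4):

    -2 l_REML(s) = log det M(s) + (n - p) * (1 + log(2 pi r2 / (n - p)))

where ``M`` is the blocked normal-equation matrix of the penalized
least-squares problem and ``r2`` its minimized penalized residual sum of
squares.  ``M`` is sparse; one factorization per objective evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, sparse
from scipy.sparse.linalg import splu

_LOG2PI = float(np.log(2 * np.pi))

#: a ratio below this (relative) is treated as a boundary (zero-variance) fit
BOUNDARY_TOL = 1e-4


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the optimizer trace message."""


@dataclass
class RandomComponent:
    """One independent random-effect block.

    ``indices`` assigns each observation to a level of the grouping factor
    (0..q-1); ``covariate`` optionally scales the design column (random
    slope).  The implied design matrix has one column per level.
    """

    name: str
    indices: np.ndarray
    n_levels: int
    covariate: Optional[np.ndarray] = None

    def design(self, n_obs: int) -> sparse.csr_matrix:
        data = (
            np.ones(n_obs)
            if self.covariate is None
            else np.asarray(self.covariate, dtype=float)
        )
        return sparse.csr_matrix(
            (data, (np.arange(n_obs), self.indices)),
            shape=(n_obs, self.n_levels),
        )


@dataclass
class REMLResult:
    beta: np.ndarray
    se_beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float  # residual variance
    variances: dict[str, float]  # per-component variances
    boundary: dict[str, bool]  # component at the zero boundary?
    loglik: float  # REML log-likelihood
    converged: bool
    n_obs: int
    n_fixed: int
    deviance: float = field(repr=False, default=float("nan"))


def _logdet_from_splu(lu) -> float:
    # M is symmetric positive definite; diag(U) may carry permutation signs,
    # but |det| is what we need.
    diag = lu.U.diagonal()
    return float(np.sum(np.log(np.abs(diag))))


class _Profile:
    """Precomputed cross-products for fast objective evaluation."""

    def __init__(self, y, X, components: Sequence[RandomComponent]):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        self.n, self.p = n, p
        self.components = list(components)
        Zs = [c.design(n) for c in components]
        self.col_comp = np.concatenate(
            [np.full(z.shape[1], i) for i, z in enumerate(Zs)]
        )
        Z = sparse.hstack(Zs, format="csr")
        self.q = Z.shape[1]
        self.ZtZ = (Z.T @ Z).tocsr()
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _assemble(self, s: np.ndarray):
        svec = s[self.col_comp]
        D = sparse.diags(svec)
        A11 = (D @ self.ZtZ @ D + sparse.identity(self.q)).tocsc()
        B = D @ self.ZtX  # q x p, dense
        M = sparse.bmat(
            [[A11, sparse.csc_matrix(B)], [sparse.csc_matrix(B.T), sparse.csc_matrix(self.XtX)]],
            format="csc",
        )
        rhs = np.concatenate([svec * self.Zty, self.Xty])
        return A11, M, rhs

    def deviance(self, s: np.ndarray) -> float:
        s = np.abs(s)
        _, M, rhs = self._assemble(s)
        try:
            lu = splu(M)
        except RuntimeError:
            return np.inf
        b = lu.solve(rhs)
        r2 = self.yty - float(rhs @ b)
        if r2 <= 0:
            return np.inf
        nmp = self.n - self.p
        return _logdet_from_splu(lu) + nmp * (1 + _LOG2PI + np.log(r2 / nmp))

    def finish(self, s: np.ndarray, converged: bool) -> REMLResult:
        s = np.abs(s)
        A11, M, rhs = self._assemble(s)
        lu = splu(M)
        b = lu.solve(rhs)
        beta = b[self.q :]
        r2 = self.yty - float(rhs @ b)
        nmp = self.n - self.p
        sigma2 = r2 / nmp
        dev = _logdet_from_splu(lu) + nmp * (1 + _LOG2PI + np.log(sigma2))
        # Cov(beta) = sigma2 * (X' V^-1 X)^-1 via the Schur complement of M
        B = (sparse.diags(s[self.col_comp]) @ self.ZtX)
        lu11 = splu(A11)
        Rx = self.XtX - B.T @ lu11.solve(B)
        cov_beta = sigma2 * np.linalg.inv(Rx)
        se_beta = np.sqrt(np.diag(cov_beta))
        variances = {}
        boundary = {}
        smax = max(s.max(), 1.0)
        for i, comp in enumerate(self.components):
            variances[comp.name] = float(s[i] ** 2 * sigma2)
            boundary[comp.name] = bool(s[i] < BOUNDARY_TOL * smax + BOUNDARY_TOL)
        return REMLResult(
            beta=beta,
            se_beta=se_beta,
            cov_beta=cov_beta,
            sigma2=float(sigma2),
            variances=variances,
            boundary=boundary,
            loglik=-dev / 2.0,
            converged=converged,
            n_obs=self.n,
            n_fixed=self.p,
            deviance=dev,
        )


def fit_reml(
    y,
    X,
    components: Sequence[RandomComponent],
    n_starts: int = 3,
    tol: float = 1e-8,
    max_ratio: float = 1e3,
) -> REMLResult:
    """Fit the independent-components mixed model by profiled REML.

    Optimizes the SD ratios from ``n_starts`` deterministic starting points
    (1, 0.3, 3 on every component) and keeps the best optimum; ratios are
    bounded in [0, max_ratio], so zero-variance (boundary) solutions are
    admissible and flagged rather than errors.
    """
    prof = _Profile(y, X, components)
    C = len(prof.components)
    if C == 0:
        raise ValueError("at least one random component is required")
    # factorization cost grows with the number of random-effect columns;
    # multi-start and high-precision polish are reserved for problems where
    # they are cheap (the deviance is unimodal in practice, so one start
    # suffices on large crossed designs)
    large = prof.q > 1000
    n_use = 1 if large else max(1, n_starts)
    starts = [np.full(C, v) for v in (1.0, 0.3, 3.0)[:n_use]]
    best = None
    ok = False
    messages = []
    for s0 in starts:
        res = optimize.minimize(
            prof.deviance,
            s0,
            method="L-BFGS-B",
            bounds=[(0.0, max_ratio)] * C,
            options={"ftol": tol, "gtol": 1e-12, "maxiter": 500},
        )
        messages.append(str(res.message))
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        ok = ok or res.success
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(
            "REML optimization failed from all starts: " + "; ".join(messages)
        )
    if not large:
        # derivative-free polish: the profiled deviance is flat near its
        # optimum, so a short Nelder-Mead pass sharpens the last digits
        polish = optimize.minimize(
            prof.deviance,
            best.x,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 300},
        )
        if np.isfinite(polish.fun) and polish.fun <= best.fun + 1e-12:
            best = polish
    return prof.finish(best.x, converged=bool(ok))
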