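"""Bayesian PCA imputation via variational EM with automatic relevance determination.

Genes are treated as data points in sample space.  A probabilistic PCA
model ``x = W z + mu + eps`` is fitted by EM; per-factor ARD precisions
prune factors that carry no signal, so the effective rank is selected
automatically.  Missing entries are re-estimated each sweep from the
posterior predictive mean given the row's observed part.
"""

from __future__ import annotations

import numpy as np

from .base import BaseMatrixImputer, row_average_fill

__all__ = ["BPCAImputer"]

_EPS = 1e-12


class BPCAImputer(BaseMatrixImputer):
    """Variational EM Bayesian PCA imputer.

    Parameters
    ----------
    n_factors : int or None
        Latent dimensionality; default ``n_samples - 1`` (ARD shrinks
        irrelevant factors).
    tol : float
        Relative-change convergence threshold on the missing cells.
    max_iter : int
        EM sweep budget; on non-convergence the best iterate is returned
        and flagged in ``diagnostics_``.
    seed : int
        Seed for the random initialisation of the loading matrix.
    """

    algorithm_id = "bpca"

    def __init__(self, n_factors: int | None = None, tol: float = 1e-4, max_iter: int = 100, seed: int = 0):
        self.n_factors = n_factors
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    def _impute(self, X: np.ndarray) -> np.ndarray:
        n, d = X.shape
        q = self.n_factors if self.n_factors is not None else max(1, d - 1)
        if not (1 <= q <= d - 1) and d > 1:
            raise ValueError(f"n_factors must lie in [1, {d - 1}], got {q}")
        missing = np.isnan(X)
        cur = row_average_fill(X)
        rng = np.random.default_rng(self.seed)
        W = rng.normal(scale=1.0 / np.sqrt(q), size=(d, q))
        sigma2 = 1.0
        alpha = np.ones(q)
        prev_missing = cur[missing]
        converged = False
        for it in range(self.max_iter):
            mu = cur.mean(axis=0)
            Xc = cur - mu
            # E-step: posterior of the latent scores
            M = W.T @ W + sigma2 * np.eye(q)
            Minv = np.linalg.inv(M)
            Z = Xc @ W @ Minv                      # (n, q) posterior means
            Sz = sigma2 * Minv                     # shared posterior covariance
            # M-step with ARD regularisation of the loadings
            A = Z.T @ Z + n * Sz + sigma2 * np.diag(alpha)
            W = np.linalg.solve(A.T, (Xc.T @ Z).T).T
            WtW = W.T @ W
            resid = (
                np.sum(Xc * Xc)
                - 2.0 * np.sum((Z @ W.T) * Xc)
                + n * np.trace(Sz @ WtW)
                + np.sum((Z @ WtW) * Z)
            )
            sigma2 = max(resid / (n * d), _EPS)
            alpha = d / (np.sum(W * W, axis=0) + _EPS)
            # predictive refill of the missing cells, row by row
            for g in np.flatnonzero(missing.any(axis=1)):
                obs = ~missing[g]
                Wo = W[obs]
                Mo = Wo.T @ Wo + sigma2 * np.eye(q)
                z = np.linalg.solve(Mo, Wo.T @ (cur[g, obs] - mu[obs]))
                cur[g, ~obs] = W[~obs] @ z + mu[~obs]
            change = np.linalg.norm(cur[missing] - prev_missing)
            scale = max(np.linalg.norm(prev_missing), _EPS)
            prev_missing = cur[missing]
            self.diagnostics_["iterations"] = it + 1
            if change / scale < self.tol:
                converged = True
                break
        self.diagnostics_["converged"] = converged
        return cur
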