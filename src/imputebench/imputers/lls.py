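"""Local least squares imputation family: LLS, SLLS, ILLS and shrinkage variants.

A target gene's observed part is expressed as a linear combination of the
corresponding parts of its k nearest neighbour genes (minimum-norm least
squares); the same combination of the neighbours' values fills the target's
missing samples.  The sequential variant lets imputed genes re-enter the
neighbour pool; the iterative variant repeats the fit from a row-average
start until the estimates stabilise.  The shrinkage variants scale the
fitted coefficient vector by a positive-part James-Stein factor before
prediction, damping overfitted local regressions.
"""

from __future__ import annotations

import numpy as np

from .base import BaseMatrixImputer, row_average_fill

__all__ = ["LLSImputer", "SequentialLLSImputer", "IterativeLLSImputer", "default_lls_k"]

_EPS = 1e-12


def default_lls_k(n_genes: int) -> int:
    """Default neighbourhood size: 10% of the genes, clipped to [5, 150]."""
    return int(min(max(round(0.1 * n_genes), 5), 150))


def _js_shrinkage(w: np.ndarray, residual: np.ndarray, n_obs: int) -> float:
    """Positive-part James-Stein factor for a local fit's coefficients.

    ``c = clip(1 - (k - 2) * sigma^2 / ||w||^2, 0, 1)`` with ``sigma^2`` the
    residual variance of the fit; k <= 2 leaves the coefficients untouched.
    """
    k = w.size
    if k <= 2:
        return 1.0
    dof = max(1, n_obs - k)
    sigma2 = float(residual @ residual) / dof
    norm2 = float(w @ w)
    if norm2 < _EPS:
        return 1.0
    return float(np.clip(1.0 - (k - 2) * sigma2 / norm2, 0.0, 1.0))


def _solve_local(
    target_obs: np.ndarray,
    neigh_obs: np.ndarray,
    neigh_miss: np.ndarray,
    shrinkage: bool,
) -> tuple[np.ndarray, bool]:
    """Fit w minimising ||w @ neigh_obs - target_obs|| (minimum-norm) and predict.

    Returns the predicted missing values and whether the neighbour block was
    rank deficient (pseudoinverse engaged).
    """
    # lstsq on the transposed system gives the minimum-norm coefficient vector
    w, _, rank, _ = np.linalg.lstsq(neigh_obs.T, target_obs, rcond=None)
    deficient = rank < min(neigh_obs.shape)
    if shrinkage:
        residual = target_obs - w @ neigh_obs
        w = _js_shrinkage(w, residual, target_obs.size) * w
    return w @ neigh_miss, deficient


def _nearest(target: np.ndarray, pool_rows: np.ndarray, pool_vals: np.ndarray, obs: np.ndarray, k: int) -> np.ndarray:
    """Indices into ``pool_rows`` of the k nearest genes on the observed columns."""
    diffs = pool_vals[:, obs] - target[obs]
    d = np.sqrt(np.sum(diffs * diffs, axis=1))
    order = np.lexsort((pool_rows, d))
    return order[:k]


class LLSImputer(BaseMatrixImputer):
    """Local least squares imputation.

    Neighbours of a target gene are drawn from the genes with no missing
    values at all (so plain LLS never imputes from imputed noise); the k
    nearest by Euclidean distance on the target's observed samples form the
    regression block.  ``k=None`` uses :func:`default_lls_k`; if fewer
    complete genes exist, k is reduced and recorded in ``diagnostics_``.
    """

    algorithm_id = "lls"

    def __init__(self, k: int | None = None, shrinkage: bool = False):
        self.k = k
        self.shrinkage = shrinkage

    def _resolve_k(self, n_genes: int) -> int:
        k = self.k if self.k is not None else default_lls_k(n_genes)
        if k < 1:
            raise ValueError("k must be >= 1")
        return k

    def _impute(self, X: np.ndarray) -> np.ndarray:
        k = self._resolve_k(X.shape[0])
        out = X.copy()
        fallback = row_average_fill(X)
        missing = np.isnan(X)
        complete_rows = np.flatnonzero(~missing.any(axis=1))
        for g in np.flatnonzero(missing.any(axis=1)):
            obs = ~missing[g]
            miss = missing[g]
            if complete_rows.size == 0:
                out[g, miss] = fallback[g, miss]
                self._fallback(int(miss.sum()))
                continue
            if complete_rows.size < k:
                self.diagnostics_["k_reduced"] = int(complete_rows.size)
            sel = _nearest(X[g], complete_rows, X[complete_rows], obs, k)
            block = X[complete_rows[sel]]
            pred, deficient = _solve_local(X[g, obs], block[:, obs], block[:, miss], self.shrinkage)
            if deficient:
                self.diagnostics_["rank_deficient"] = self.diagnostics_.get("rank_deficient", 0) + 1
            out[g, miss] = pred
        return out


class SequentialLLSImputer(BaseMatrixImputer):
    """Sequential LLS: ascending missing-count order, imputed genes re-enter the pool."""

    algorithm_id = "slls"

    def __init__(self, k: int | None = None, shrinkage: bool = False):
        self.k = k
        self.shrinkage = shrinkage

    def _impute(self, X: np.ndarray) -> np.ndarray:
        k = LLSImputer(k=self.k)._resolve_k(X.shape[0])
        out = X.copy()
        fallback = row_average_fill(X)
        missing = np.isnan(X)
        counts = missing.sum(axis=1)
        pool = list(np.flatnonzero(counts == 0))
        order = np.lexsort((np.arange(X.shape[0]), counts))
        for g in order:
            if counts[g] == 0:
                continue
            obs = ~missing[g]
            miss = missing[g]
            if not pool:
                out[g, miss] = fallback[g, miss]
                self._fallback(int(miss.sum()))
                pool.append(int(g))
                continue
            rows = np.asarray(pool)
            sel = _nearest(out[g], rows, out[rows], obs, k)
            block = out[rows[sel]]
            pred, _ = _solve_local(out[g, obs], block[:, obs], block[:, miss], self.shrinkage)
            out[g, miss] = pred
            pool.append(int(g))
        return out


class IterativeLLSImputer(BaseMatrixImputer):
    """Iterative LLS: repeat the local fits from a row-average start until stable."""

    algorithm_id = "ills"

    def __init__(self, k: int | None = None, shrinkage: bool = False, tol: float = 1e-4, max_iter: int = 100):
        self.k = k
        self.shrinkage = shrinkage
        self.tol = tol
        self.max_iter = max_iter

    def _impute(self, X: np.ndarray) -> np.ndarray:
        k = LLSImputer(k=self.k)._resolve_k(X.shape[0])
        missing = np.isnan(X)
        cur = row_average_fill(X)
        n = X.shape[0]
        targets = np.flatnonzero(missing.any(axis=1))
        prev_missing = cur[missing]
        for it in range(self.max_iter):
            new = cur.copy()
            for g in targets:
                obs = ~missing[g]
                miss = missing[g]
                others = np.concatenate([np.arange(g), np.arange(g + 1, n)])
                if others.size == 0:
                    continue
                sel = _nearest(cur[g], others, cur[others], obs, k)
                block = cur[others[sel]]
                pred, _ = _solve_local(cur[g, obs], block[:, obs], block[:, miss], self.shrinkage)
                new[g, miss] = pred
            cur = new
            change = np.linalg.norm(cur[missing] - prev_missing)
            scale = max(np.linalg.norm(prev_missing), _EPS)
            prev_missing = cur[missing]
            self.diagnostics_["iterations"] = it + 1
            if change / scale < self.tol:
                break
        return cur
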