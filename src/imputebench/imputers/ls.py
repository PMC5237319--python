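"""Least-squares imputation (gene-based regression on correlated neighbours)."""

from __future__ import annotations

import numpy as np

from .base import BaseMatrixImputer, row_average_fill

__all__ = ["LSImputer"]

#: minimum jointly observed samples for a usable correlation/regression
MIN_SHARED = 3


class LSImputer(BaseMatrixImputer):
    """Regression-based imputation on the most correlated genes.

    For each missing cell, the ``k`` genes most correlated (absolute
    Pearson correlation over jointly observed samples, at least
    ``MIN_SHARED`` shared) with the target and observed in the missing
    sample each contribute a simple least-squares prediction
    ``target ~ a + b * neighbour``; the predictions are combined with
    weights ``(r^2 / (1 - r^2 + eps))^2`` normalised to sum one, so
    near-perfectly correlated neighbours dominate.  Cells with no usable
    neighbour fall back to the row average.
    """

    algorithm_id = "ls"

    def __init__(self, k: int = 10, eps: float = 1e-6):
        self.k = k
        self.eps = eps

    def _impute(self, X: np.ndarray) -> np.ndarray:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        out = X.copy()
        fallback = row_average_fill(X)
        missing = np.isnan(X)
        observed = ~missing
        for g in np.flatnonzero(missing.any(axis=1)):
            r, a, b, usable = self._fit_all(X, observed, g)
            for c in np.flatnonzero(missing[g]):
                elig = usable & observed[:, c]
                rows = np.flatnonzero(elig)
                if rows.size == 0:
                    out[g, c] = fallback[g, c]
                    self._fallback()
                    continue
                # k best by |r|; ties broken by ascending row index
                order = np.lexsort((rows, -np.abs(r[rows])))[: self.k]
                sel = rows[order]
                preds = a[sel] + b[sel] * X[sel, c]
                r2 = r[sel] ** 2
                w = (r2 / (1.0 - r2 + self.eps)) ** 2
                if w.sum() < 1e-300:
                    w = np.ones_like(w)
                out[g, c] = float(np.sum(w * preds) / np.sum(w))
        return out

    def _fit_all(
        self, X: np.ndarray, observed: np.ndarray, g: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Correlation and regression of the target on every candidate gene.

        All moments are taken over the columns jointly observed by the
        target and the candidate; candidates with fewer than MIN_SHARED
        shared columns or zero variance on them are flagged unusable.
        """
        y = X[g]
        shared = observed & observed[g][None, :]          # (n, s)
        n_sh = shared.sum(axis=1).astype(float)
        Xw = np.where(shared, X, 0.0)
        Yw = np.where(shared, y[None, :], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mx = Xw.sum(1) / n_sh
            my = Yw.sum(1) / n_sh
            vx = np.maximum((Xw * Xw).sum(1) / n_sh - mx * mx, 0.0)
            vy = np.maximum((Yw * Yw).sum(1) / n_sh - my * my, 0.0)
            cov = (Xw * Yw).sum(1) / n_sh - mx * my
            r = cov / np.sqrt(vx * vy)
            b = cov / vx
        a = my - b * mx
        usable = (n_sh >= MIN_SHARED) & (vx > 1e-20) & (vy > 1e-20) & np.isfinite(r)
        usable[g] = False
        r = np.clip(np.where(np.isfinite(r), r, 0.0), -1.0, 1.0)
        return r, a, b, usable
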