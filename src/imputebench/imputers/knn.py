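"""K-nearest-neighbour imputation family: KNN, SKNN (sequential), IKNN (iterative).

All three share the same local estimate: a missing cell is the
inverse-distance-weighted mean of the values the k most similar genes take
in that sample.  Similarity is Euclidean distance over jointly observed
samples, normalised by the number of shared samples so genes with different
overlap sizes are comparable.  Ties are broken by ascending row index so
results are deterministic.
"""

from __future__ import annotations

import numpy as np

from .base import BaseMatrixImputer, row_average_fill

__all__ = ["KNNImputer", "SequentialKNNImputer", "IterativeKNNImputer"]

_EPS = 1e-12


def _distances_to(target: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """RMS distance of each candidate row to the target over jointly observed
    positions; NaN where no position is shared."""
    diffs = candidates - target[None, :]  # NaN wherever either side is missing
    shared = (~np.isnan(diffs)).sum(axis=1)
    sq = np.nansum(diffs * diffs, axis=1)
    return np.where(shared > 0, np.sqrt(sq / np.maximum(shared, 1)), np.nan)


def _select_k(distances: np.ndarray, candidate_rows: np.ndarray, k: int) -> np.ndarray:
    """Positions of the k nearest candidates, ties broken by ascending row index."""
    return np.lexsort((candidate_rows, distances))[:k]


def _weighted_mean(distances: np.ndarray, values: np.ndarray) -> float:
    """Inverse-distance-weighted mean of the selected neighbours' values."""
    w = 1.0 / (distances + _EPS)
    return float(np.sum(w * values) / np.sum(w))


class KNNImputer(BaseMatrixImputer):
    """Classical gene-wise KNN imputation.

    For a target gene with missing cells, candidate genes are those observed
    at all of the target's missing samples; each missing cell becomes the
    inverse-distance-weighted mean of the k nearest candidates' values in
    that sample.  Cells with no eligible candidate fall back to the gene's
    row average (counted in ``diagnostics_``).
    """

    algorithm_id = "knn"

    def __init__(self, k: int = 10):
        self.k = k

    def _impute(self, X: np.ndarray) -> np.ndarray:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        out = X.copy()
        fallback = row_average_fill(X)
        missing = np.isnan(X)
        for g in np.flatnonzero(missing.any(axis=1)):
            miss_cols = np.flatnonzero(missing[g])
            eligible = ~missing[:, miss_cols].any(axis=1)
            eligible[g] = False
            rows = np.flatnonzero(eligible)
            dists = _distances_to(X[g], X[rows])
            ok = ~np.isnan(dists)
            rows, dists = rows[ok], dists[ok]
            if rows.size == 0:
                out[g, miss_cols] = fallback[g, miss_cols]
                self._fallback(len(miss_cols))
                continue
            sel = _select_k(dists, rows, self.k)
            for c in miss_cols:
                out[g, c] = _weighted_mean(dists[sel], X[rows[sel], c])
        return out


class SequentialKNNImputer(BaseMatrixImputer):
    """Sequential KNN: genes imputed in ascending missing-count order.

    Once a gene is completed it joins the candidate pool, so later (worse)
    genes can borrow from earlier imputed ones.  The pool starts with the
    originally complete genes; if none exist, the first processed gene falls
    back to its row average to seed the pool.
    """

    algorithm_id = "sknn"

    def __init__(self, k: int = 10):
        self.k = k

    def _impute(self, X: np.ndarray) -> np.ndarray:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        out = X.copy()
        fallback = row_average_fill(X)
        missing = np.isnan(X)
        counts = missing.sum(axis=1)
        pool = list(np.flatnonzero(counts == 0))
        order = np.lexsort((np.arange(X.shape[0]), counts))
        for g in order:
            if counts[g] == 0:
                continue
            miss_cols = np.flatnonzero(missing[g])
            if not pool:
                out[g, miss_cols] = fallback[g, miss_cols]
                self._fallback(len(miss_cols))
                pool.append(int(g))
                continue
            rows = np.asarray(pool)
            dists = _distances_to(out[g], out[rows])
            sel = _select_k(dists, rows, self.k)
            for c in miss_cols:
                out[g, c] = _weighted_mean(dists[sel], out[rows[sel], c])
            pool.append(int(g))
        return out


class IterativeKNNImputer(BaseMatrixImputer):
    """Iterative KNN: row-average start, complete-matrix KNN re-estimation.

    Starting from a row-average fill, the originally missing cells are
    repeatedly re-estimated by KNN on the current complete matrix (distances
    over all samples) until the largest relative change drops below ``tol``
    or ``max_iter`` is reached.
    """

    algorithm_id = "iknn"

    def __init__(self, k: int = 10, tol: float = 1e-4, max_iter: int = 100):
        self.k = k
        self.tol = tol
        self.max_iter = max_iter

    def _impute(self, X: np.ndarray) -> np.ndarray:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        missing = np.isnan(X)
        cur = row_average_fill(X)
        n = X.shape[0]
        targets = np.flatnonzero(missing.any(axis=1))
        for it in range(self.max_iter):
            new = cur.copy()
            for g in targets:
                others = np.concatenate([np.arange(g), np.arange(g + 1, n)])
                diffs = cur[others] - cur[g]
                dists = np.sqrt(np.mean(diffs * diffs, axis=1))
                sel = _select_k(dists, others, self.k)
                for c in np.flatnonzero(missing[g]):
                    new[g, c] = _weighted_mean(dists[sel], cur[others[sel], c])
            denom = max(float(np.max(np.abs(cur[missing]))), _EPS)
            delta = float(np.max(np.abs(new[missing] - cur[missing]))) / denom
            cur = new
            self.diagnostics_["iterations"] = it + 1
            if delta < self.tol:
                break
        return cur
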