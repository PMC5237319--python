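"""SVD imputation: EM-style iterative low-rank approximation."""

from __future__ import annotations

import numpy as np

from .base import BaseMatrixImputer, row_average_fill

__all__ = ["SVDImputer"]


class SVDImputer(BaseMatrixImputer):
    """Fill missing cells from a truncated-SVD reconstruction.

    Missing cells start at the gene's row average; then the matrix is
    repeatedly replaced by its best rank-``rank`` approximation at the
    missing cells only, until the relative Frobenius change of those cells
    drops below ``tol`` or ``max_iter`` is reached.  ``rank=None`` defaults
    to ``max(1, round(0.2 * n_samples))``.
    """

    algorithm_id = "svd"

    def __init__(self, rank: int | None = None, tol: float = 1e-4, max_iter: int = 100):
        self.rank = rank
        self.tol = tol
        self.max_iter = max_iter

    def _resolve_rank(self, shape: tuple[int, int]) -> int:
        rank = self.rank
        if rank is None:
            rank = max(1, int(round(0.2 * shape[1])))
        if not (1 <= rank <= min(shape)):
            raise ValueError(f"rank must lie in [1, {min(shape)}], got {rank}")
        return rank

    def _impute(self, X: np.ndarray) -> np.ndarray:
        rank = self._resolve_rank(X.shape)
        missing = np.isnan(X)
        cur = row_average_fill(X)
        prev_missing = cur[missing]
        for it in range(self.max_iter):
            U, s, Vt = np.linalg.svd(cur, full_matrices=False)
            approx = (U[:, :rank] * s[:rank]) @ Vt[:rank]
            cur[missing] = approx[missing]
            change = np.linalg.norm(cur[missing] - prev_missing)
            scale = max(np.linalg.norm(prev_missing), 1e-12)
            prev_missing = cur[missing]
            self.diagnostics_["iterations"] = it + 1
            if change / scale < self.tol:
                break
        return cur
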