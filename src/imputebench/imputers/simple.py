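"""Baseline imputers: zero fill and row average."""

from __future__ import annotations

import numpy as np

from .base import BaseMatrixImputer, row_average_fill

__all__ = ["ZeroImputer", "RowAverageImputer"]


class ZeroImputer(BaseMatrixImputer):
    """Replace every missing entry with 0 (the classical naive baseline)."""

    algorithm_id = "zero"

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X[np.isnan(X)] = 0.0
        return X


class RowAverageImputer(BaseMatrixImputer):
    """Replace missing entries with the mean of the gene's observed values."""

    algorithm_id = "row_average"

    def _impute(self, X: np.ndarray) -> np.ndarray:
        return row_average_fill(X)
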