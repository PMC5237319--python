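"""Common estimator machinery for the imputation algorithms.

Every algorithm is a scikit-learn style transformer: hyperparameters are
``__init__`` keyword arguments (so ``get_params``/``set_params``,
``clone`` and pipeline composition work), ``fit`` validates the input and
``transform`` returns a completed copy of a genes x samples matrix whose
missing entries are ``NaN``.  Imputation is stateless with respect to
training data -- ``fit_transform(X)`` on the matrix to be completed is the
normal call pattern, exactly as with :class:`sklearn.impute.KNNImputer`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["BaseMatrixImputer", "ImputationError", "row_average_fill"]


class ImputationError(RuntimeError):
    """An algorithm could not complete the matrix."""


def row_average_fill(X: np.ndarray) -> np.ndarray:
    """Fill NaNs with the mean of each row's observed entries.

    Rows with no observed entry fall back to the grand observed mean
    (0 if the whole matrix is missing); used as initialisation and as the
    universal per-cell fallback.
    """
    X = np.array(X, dtype=np.float64)
    missing = np.isnan(X)
    if not missing.any():
        return X
    with np.errstate(invalid="ignore"):
        row_means = np.nanmean(X, axis=1)
    grand = np.nanmean(X) if not np.isnan(X).all() else 0.0
    row_means = np.where(np.isnan(row_means), grand, row_means)
    X[missing] = np.broadcast_to(row_means[:, None], X.shape)[missing]
    return X


class BaseMatrixImputer(TransformerMixin, BaseEstimator):
    """Base class: validation, the observed-cell guarantee and diagnostics.

    Subclasses implement ``_impute(X)`` receiving a float matrix with NaNs
    and returning a complete matrix of the same shape.  ``transform``
    enforces the observed-cell preservation invariant by overwriting
    observed entries from the input afterwards, making the invariant
    algorithm-independent.
    """

    #: registry identifier, set by each subclass
    algorithm_id: str = "base"

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = self._validate(X)
        self.diagnostics_ = {"fallback_cells": 0, "iterations": 0}
        missing = np.isnan(X)
        if not missing.any():
            return X.copy()
        out = np.asarray(self._impute(X.copy()), dtype=np.float64)
        if out.shape != X.shape:
            raise ImputationError(
                f"{self.algorithm_id}: internal shape mismatch {out.shape} != {X.shape}"
            )
        out[~missing] = X[~missing]  # bit-exact preservation of observed cells
        if np.isnan(out).any() or np.isinf(out).any():
            raise ImputationError(f"{self.algorithm_id}: non-finite values remain after imputation")
        return out

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X).transform(X)

    # -- helpers ----------------------------------------------------------
    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
            raise ValueError("expected a non-empty 2-D genes x samples matrix")
        if np.isinf(X).any():
            raise ValueError("matrix contains inf values")
        if np.isnan(X).all(axis=1).any():
            raise ImputationError("a gene with no observed values cannot be imputed")
        return X

    def _impute(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def _fallback(self, n_cells: int = 1) -> None:
        self.diagnostics_["fallback_cells"] += n_cells
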