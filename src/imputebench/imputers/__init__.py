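"""Imputation algorithms behind one uniform contract.

The registry exposes the twelve published algorithms (two global: SVD,
BPCA; ten local: KNN, SKNN, IKNN, LS, LLS, SLLS, ILLS and their shrinkage
variants) plus the two naive baselines (zero fill and row average).  Each
is a scikit-learn style transformer; :func:`impute` is the uniform entry
point that runs one on a :class:`~imputebench.matrix_io.MaskedMatrix` and
returns a validated :class:`~imputebench.matrix_io.ImputationResult`.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field
from typing import Optional, Type

from ..matrix_io import ImputationResult, MaskedMatrix
from .base import BaseMatrixImputer, ImputationError, row_average_fill
from .bpca import BPCAImputer
from .knn import IterativeKNNImputer, KNNImputer, SequentialKNNImputer
from .lls import IterativeLLSImputer, LLSImputer, SequentialLLSImputer, default_lls_k
from .ls import LSImputer
from .plugin import PluginContract, PluginError, run_plugin
from .simple import RowAverageImputer, ZeroImputer
from .svd import SVDImputer

__all__ = [
    "BaseMatrixImputer",
    "ImputationError",
    "ImputerSpec",
    "PluginContract",
    "PluginError",
    "REGISTRY",
    "available_algorithms",
    "make_imputer",
    "impute",
    "run_plugin",
    "row_average_fill",
    "default_lls_k",
    "ZeroImputer",
    "RowAverageImputer",
    "KNNImputer",
    "SequentialKNNImputer",
    "IterativeKNNImputer",
    "SVDImputer",
    "BPCAImputer",
    "LSImputer",
    "LLSImputer",
    "SequentialLLSImputer",
    "IterativeLLSImputer",
    "ShrinkageLLSImputer",
    "ShrinkageSLLSImputer",
    "ShrinkageILLSImputer",
]


class ShrinkageLLSImputer(LLSImputer):
    """LLS with positive-part James-Stein shrinkage of the local coefficients."""

    algorithm_id = "shrink_lls"

    def __init__(self, k: int | None = None):
        super().__init__(k=k, shrinkage=True)


class ShrinkageSLLSImputer(SequentialLLSImputer):
    """Sequential LLS with coefficient shrinkage."""

    algorithm_id = "shrink_slls"

    def __init__(self, k: int | None = None):
        super().__init__(k=k, shrinkage=True)


class ShrinkageILLSImputer(IterativeLLSImputer):
    """Iterative LLS with coefficient shrinkage."""

    algorithm_id = "shrink_ills"

    def __init__(self, k: int | None = None, tol: float = 1e-4, max_iter: int = 100):
        super().__init__(k=k, shrinkage=True, tol=tol, max_iter=max_iter)


#: the 2 baselines + 12 published algorithms, keyed by registry id
REGISTRY: dict[str, Type[BaseMatrixImputer]] = {
    "zero": ZeroImputer,
    "row_average": RowAverageImputer,
    "svd": SVDImputer,
    "bpca": BPCAImputer,
    "knn": KNNImputer,
    "sknn": SequentialKNNImputer,
    "iknn": IterativeKNNImputer,
    "ls": LSImputer,
    "lls": LLSImputer,
    "slls": SequentialLLSImputer,
    "ills": IterativeLLSImputer,
    "shrink_lls": ShrinkageLLSImputer,
    "shrink_slls": ShrinkageSLLSImputer,
    "shrink_ills": ShrinkageILLSImputer,
}

BASELINE_IDS = ("zero", "row_average")


def available_algorithms() -> list[str]:
    """Registry ids of all built-in algorithms (baselines first)."""
    return list(REGISTRY)


@dataclass
class ImputerSpec:
    """Selection of one algorithm with optional hyperparameter overrides."""

    algorithm_id: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    plugin: Optional[PluginContract] = None

    def __post_init__(self) -> None:
        if self.algorithm_id.startswith("plugin:"):
            if self.plugin is None:
                raise ValueError(f"{self.algorithm_id}: plugin contract required")
        elif self.algorithm_id not in REGISTRY:
            raise ValueError(
                f"unknown algorithm {self.algorithm_id!r}; known: {', '.join(REGISTRY)}"
            )


def make_imputer(algorithm_id: str, seed: int = 0, **hyperparameters) -> BaseMatrixImputer:
    """Instantiate a registered imputer, rejecting unknown hyperparameter keys."""
    if algorithm_id not in REGISTRY:
        raise ValueError(f"unknown algorithm {algorithm_id!r}; known: {', '.join(REGISTRY)}")
    cls = REGISTRY[algorithm_id]
    accepted = set(inspect.signature(cls.__init__).parameters) - {"self"}
    unknown = set(hyperparameters) - accepted
    if unknown:
        raise ValueError(
            f"{algorithm_id}: unknown hyperparameters {sorted(unknown)}; accepted: {sorted(accepted)}"
        )
    if "seed" in accepted and "seed" not in hyperparameters:
        hyperparameters["seed"] = seed
    return cls(**hyperparameters)


def impute(spec: ImputerSpec, masked: MaskedMatrix) -> ImputationResult:
    """Run one algorithm on one masked matrix (Step 2 of the procedure).

    Dispatches to the registered estimator (or the plugin runner), enforces
    the observed-cell preservation invariant and wraps the completed matrix
    with diagnostics.  Deterministic given ``(spec, masked)``.
    """
    if spec.plugin is not None:
        return run_plugin(spec.plugin, masked)
    est = make_imputer(spec.algorithm_id, seed=spec.seed, **spec.hyperparameters)
    imputed = est.fit_transform(masked.values)
    return ImputationResult(spec.algorithm_id, masked, imputed, dict(est.diagnostics_))
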