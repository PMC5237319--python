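"""The four-step simulation engine.

For every dataset, simulation run and missing percentage: (1) draw an MCAR
mask, (2) impute it with every selected algorithm, (3) score every imputed
matrix with every selected index, (4) repeat B times and average — giving
the final score ``S_ij(k)`` of algorithm ``k`` for index ``i`` and dataset
``j`` as the mean of ``|percentages| * B`` raw scores.

Masks are shared across algorithms within a run by default (paired design:
every algorithm sees the identical testing matrix), and each imputed matrix
is scored once per index rather than re-imputed.  All randomness is derived
from ``master_seed``, so a study is bit-reproducible.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .imputers import ImputerSpec, impute
from .indices import INDEX_IDS, compute_index
from .masking import DEFAULT_PERCENTAGES, derive_seed, make_mask
from .matrix_io import ExpressionMatrix

__all__ = ["EvalConfig", "ScoreTable", "evaluate_cell", "evaluate_study"]


@dataclass
class EvalConfig:
    """Study configuration: what to evaluate and how many runs."""

    datasets: list[tuple[str, ExpressionMatrix]]
    algorithms: list[ImputerSpec]
    indices: tuple[str, ...] = INDEX_IDS
    scores: tuple[str, ...] = ("ors", "ons")
    B: int = 25
    percentages: tuple[float, ...] = DEFAULT_PERCENTAGES
    master_seed: int = 0
    paired_masks: bool = True
    index_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.B < 1:
            raise ValueError("B (simulation runs per percentage) must be >= 1")
        if not self.datasets:
            raise ValueError("at least one dataset required")
        if not self.algorithms:
            raise ValueError("at least one algorithm required")
        if not self.indices:
            raise ValueError("at least one index required")
        if not self.scores:
            raise ValueError("at least one comprehensive score required")
        for idx in self.indices:
            if idx not in INDEX_IDS:
                raise ValueError(f"unknown index {idx!r}")
        for sc in self.scores:
            if sc not in ("ors", "ons"):
                raise ValueError(f"unknown comprehensive score {sc!r}")
        if not self.percentages:
            raise ValueError("at least one missing percentage required")
        ids = [s.algorithm_id for s in self.algorithms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate algorithm ids in config")
        for _, m in self.datasets:
            m.require_complete()


@dataclass
class ScoreTable:
    """Final scores S_ij(k) and the raw per-run scores behind them.

    ``S[i, j, k]`` is the mean of the ``|percentages| * B`` raw scores in
    ``raw[i, j, k, :, :]`` (NaN where the algorithm failed).
    """

    index_ids: list[str]
    dataset_ids: list[str]
    algorithm_ids: list[str]
    percentages: tuple[float, ...]
    S: np.ndarray          # (I, J, m)
    raw: np.ndarray        # (I, J, m, P, B)
    failed: np.ndarray     # (J, m) bool: algorithm failed on that dataset
    mask_checksums: dict = field(default_factory=dict)

    @property
    def B(self) -> int:
        return self.raw.shape[4]

    def long_frame(self) -> pd.DataFrame:
        """Raw scores in long format (dataset, algorithm, index, run, percentage)."""
        rows = []
        I, J, m, P, B = self.raw.shape
        for i in range(I):
            for j in range(J):
                for k in range(m):
                    for p in range(P):
                        for b in range(B):
                            rows.append(
                                (
                                    self.dataset_ids[j],
                                    self.algorithm_ids[k],
                                    self.index_ids[i],
                                    b,
                                    self.percentages[p],
                                    self.raw[i, j, k, p, b],
                                )
                            )
        return pd.DataFrame(
            rows, columns=["dataset", "algorithm", "index", "run", "percentage", "raw_score"]
        )

    def summary_frame(self) -> pd.DataFrame:
        """Final S_ij(k) in long format."""
        rows = []
        for i, idx in enumerate(self.index_ids):
            for j, ds in enumerate(self.dataset_ids):
                for k, alg in enumerate(self.algorithm_ids):
                    rows.append((idx, ds, alg, self.S[i, j, k]))
        return pd.DataFrame(rows, columns=["index", "dataset", "algorithm", "S"])


def _score_one(
    index_id: str,
    complete: ExpressionMatrix,
    result,
    masked,
    index_params: dict,
    cpp_seed: int,
) -> float:
    params = dict(index_params.get(index_id, {}))
    if index_id == "inv_nrmse":
        return compute_index(index_id, complete, result, mask=masked, **params).value
    if index_id == "cpp":
        params.setdefault("seed", cpp_seed)
    return compute_index(index_id, complete, result, **params).value


def evaluate_study(config: EvalConfig, progress: bool = False) -> ScoreTable:
    """Run the full simulation study and fill the (I x J x m) score tensor."""
    config.validate()
    I, J, m = len(config.indices), len(config.datasets), len(config.algorithms)
    P, B = len(config.percentages), config.B
    raw = np.full((I, J, m, P, B), np.nan)
    failed = np.zeros((J, m), dtype=bool)
    checksums: dict[str, int] = {}

    for j, (ds_id, matrix) in enumerate(config.datasets):
        for b in range(B):
            for p, pct in enumerate(config.percentages):
                run_seed = derive_seed(config.master_seed, j, b, p)
                shared_mask = (
                    make_mask(matrix, pct, run_seed) if config.paired_masks else None
                )
                for k, spec in enumerate(config.algorithms):
                    masked = shared_mask
                    if masked is None:
                        masked = make_mask(matrix, pct, derive_seed(config.master_seed, j, b, p, k + 1))
                    key = f"{ds_id}/run{b}/p{pct:g}" + ("" if config.paired_masks else f"/{spec.algorithm_id}")
                    checksums.setdefault(key, zlib.crc32(np.packbits(masked.mask).tobytes()))
                    try:
                        result = impute(spec, masked)
                    except Exception as exc:  # failure isolation: cells, not study
                        failed[j, k] = True
                        warnings.warn(
                            f"algorithm {spec.algorithm_id} failed on dataset {ds_id}, "
                            f"run {b}, percentage {pct:g}: {exc}"
                        )
                        continue
                    for i, index_id in enumerate(config.indices):
                        raw[i, j, k, p, b] = _score_one(
                            index_id, matrix, result, masked, config.index_params, run_seed
                        )
                if progress:
                    print(f"[{ds_id}] run {b + 1}/{B} pct {pct:g} done", flush=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells of failed algorithms
        S = np.nanmean(raw, axis=(3, 4))
    S[:, failed] = np.nan  # a cell is failed if any of its runs failed
    raw[:, failed, :, :] = np.nan
    return ScoreTable(
        list(config.indices),
        [ds_id for ds_id, _ in config.datasets],
        [s.algorithm_id for s in config.algorithms],
        tuple(config.percentages),
        S,
        raw,
        failed,
        checksums,
    )


def evaluate_cell(
    complete: ExpressionMatrix,
    spec: ImputerSpec,
    index_id: str,
    config: Optional[EvalConfig] = None,
    **config_kwargs,
) -> tuple[float, np.ndarray]:
    """Final score of one (dataset, algorithm, index) cell plus its raw scores.

    Convenience wrapper around :func:`evaluate_study` for a single cell;
    the returned raw scores form a (P, B) array whose mean is the score.
    """
    if config is None:
        config = EvalConfig(datasets=[("dataset", complete)], algorithms=[spec],
                            indices=(index_id,), **config_kwargs)
    table = evaluate_study(config)
    return float(table.S[0, 0, 0]), table.raw[0, 0, 0]
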