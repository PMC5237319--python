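"""External-executable plugin imputers.

A user algorithm is any executable obeying the matrix-in/matrix-out
contract: it is invoked as ``executable [args...] <input.tsv> <output.tsv>``,
reads a TSV expression matrix with ``NA`` tokens at the missing cells and
writes a complete matrix with identical gene/sample IDs.  Output is
validated: no missing cells may remain and observed cells must be unchanged
to within 1e-9 (then snapped back bit-exactly, like every built-in).
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..matrix_io import ExpressionMatrix, ImputationResult, MaskedMatrix, read_matrix, write_matrix

__all__ = ["PluginContract", "PluginError", "run_plugin", "OBSERVED_TOLERANCE"]

OBSERVED_TOLERANCE = 1e-9
DEFAULT_TIMEOUT = 3600.0


class PluginError(RuntimeError):
    """A plugin violated the matrix-in/matrix-out contract."""


@dataclass
class PluginContract:
    """Declaration of one external imputation executable."""

    name: str
    executable: str
    args: tuple[str, ...] = ()
    timeout: float = DEFAULT_TIMEOUT

    @property
    def algorithm_id(self) -> str:
        return f"plugin:{self.name}"


def run_plugin(contract: PluginContract, masked: MaskedMatrix) -> ImputationResult:
    """Run an external imputer on a masked matrix and validate its output."""
    exe = Path(contract.executable)
    if not exe.exists():
        raise PluginError(f"{contract.algorithm_id}: executable {exe} not found")
    with tempfile.TemporaryDirectory(prefix="imputebench_plugin_") as tmp:
        in_path = Path(tmp) / "input.tsv"
        out_path = Path(tmp) / "output.tsv"
        write_matrix(masked, in_path)
        cmd = [str(exe), *contract.args, str(in_path), str(out_path)]
        try:
            proc = subprocess.run(
                cmd, capture_output=True, text=True, timeout=contract.timeout
            )
        except subprocess.TimeoutExpired:
            raise PluginError(
                f"{contract.algorithm_id}: timed out after {contract.timeout} s"
            ) from None
        if proc.returncode != 0:
            raise PluginError(
                f"{contract.algorithm_id}: exit code {proc.returncode}; stderr: {proc.stderr.strip()}"
            )
        if not out_path.exists():
            raise PluginError(f"{contract.algorithm_id}: no output file written")
        result = read_matrix(out_path)
    return validate_plugin_output(contract, masked, result)


def validate_plugin_output(
    contract: PluginContract, masked: MaskedMatrix, result: ExpressionMatrix
) -> ImputationResult:
    base = masked.base
    if result.gene_ids != base.gene_ids or result.sample_ids != base.sample_ids:
        raise PluginError(f"{contract.algorithm_id}: output IDs do not match input")
    if result.n_missing:
        raise PluginError(
            f"{contract.algorithm_id}: {result.n_missing} missing cells remain in output"
        )
    obs = ~masked.mask
    drift = np.abs(result.values[obs] - base.values[obs])
    if drift.size and drift.max() > OBSERVED_TOLERANCE:
        raise PluginError(
            f"{contract.algorithm_id}: observed cell altered by {drift.max():.3g} "
            f"(tolerance {OBSERVED_TOLERANCE})"
        )
    imputed = result.values.copy()
    imputed[obs] = base.values[obs]  # snap observed cells back bit-exactly
    return ImputationResult(contract.algorithm_id, masked, imputed, {"fallback_cells": 0})
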