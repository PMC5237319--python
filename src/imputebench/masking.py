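"""MCAR mask generation: Step 1 of the simulation procedure.

From a complete matrix, entries are hidden completely at random at one of
the framework's five default percentages (1%, 3%, 5%, 8%, 10% of all cells).
Masks are redrawn (bounded retries) until every gene keeps at least two
observed entries and every sample keeps at least one, since distance and
regression steps of the imputers are undefined on fully-missing rows.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np

from .matrix_io import ExpressionMatrix, MaskedMatrix

__all__ = [
    "DEFAULT_PERCENTAGES",
    "make_mask",
    "make_testing_set",
    "write_mask_pairs",
    "MaskingError",
    "derive_seed",
]

#: the framework's default missing percentages
DEFAULT_PERCENTAGES: tuple[float, ...] = (0.01, 0.03, 0.05, 0.08, 0.10)

MAX_RETRIES = 1000


class MaskingError(RuntimeError):
    """Raised when a constraint-satisfying mask could not be drawn."""


def derive_seed(*components: int) -> int:
    """Deterministic child seed (< 2**31) from integer components.

    Stable across processes and platforms (numpy SeedSequence), so partial
    reruns of a study reproduce the same masks.
    """
    ss = np.random.SeedSequence(entropy=int(components[0]), spawn_key=tuple(int(c) for c in components[1:]))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _n_missing(percentage: float, n_cells: int) -> int:
    # round half away from zero
    return int(np.floor(percentage * n_cells + 0.5))


def make_mask(complete: ExpressionMatrix, percentage: float, seed: int) -> MaskedMatrix:
    """Draw one MCAR mask at the given fraction of all matrix cells.

    Exactly ``round(percentage * n_genes * n_samples)`` cells are hidden,
    chosen uniformly without replacement; the draw is repeated (up to 1000
    times) until the row/column retention constraint holds.  Deterministic
    given ``seed``.
    """
    complete.require_complete()
    if not (0.0 < percentage <= 0.5):
        raise ValueError(f"missing percentage must lie in (0, 0.5], got {percentage}")
    n, s = complete.shape
    n_cells = n * s
    n_miss = _n_missing(percentage, n_cells)
    if n_miss == 0:
        raise ValueError(f"percentage {percentage} yields an empty mask on a {n}x{s} matrix")
    if n_cells - n_miss < max(2 * n, s):
        raise MaskingError(
            f"cannot mask {n_miss} of {n_cells} cells on a {n}x{s} matrix "
            "while keeping >=2 observed per gene and >=1 per sample"
        )
    rng = np.random.default_rng(seed)
    for _ in range(MAX_RETRIES):
        flat = rng.choice(n_cells, size=n_miss, replace=False)
        mask = np.zeros(n_cells, dtype=bool)
        mask[flat] = True
        mask = mask.reshape(n, s)
        obs = ~mask
        if (obs.sum(axis=1) >= 2).all() and (obs.sum(axis=0) >= 1).all():
            return MaskedMatrix(complete, mask, percentage)
    raise MaskingError(
        f"no constraint-satisfying mask found for a {n}x{s} matrix at "
        f"{percentage:.0%} after {MAX_RETRIES} attempts"
    )


def make_testing_set(
    complete: ExpressionMatrix,
    run_seed: int,
    percentages: tuple[float, ...] = DEFAULT_PERCENTAGES,
) -> list[MaskedMatrix]:
    """Generate the testing matrices for one simulation run.

    One independent MCAR mask per percentage (default: the five framework
    percentages), with per-percentage seeds derived deterministically from
    ``run_seed``.
    """
    return [
        make_mask(complete, pct, derive_seed(run_seed, idx))
        for idx, pct in enumerate(percentages)
    ]


def write_mask_pairs(masked: MaskedMatrix, path: Union[str, Path]) -> Path:
    """Export the masked cells as an audit TSV of (gene_id, sample_id) pairs."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tsample_id\n")
        for gid, sid in masked.mask_pairs():
            fh.write(f"{gid}\t{sid}\n")
    return path
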