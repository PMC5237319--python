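"""Shared fixtures: small deterministic matrices and plugin executables."""

from __future__ import annotations

import sys
import textwrap

import numpy as np
import pytest

from imputebench import ExpressionMatrix, MaskedMatrix, SyntheticSpec, generate_complete


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_matrix() -> ExpressionMatrix:
    """A fixed, well-conditioned 6x4 complete matrix used by oracle tests."""
    values = np.array(
        [
            [4.1, 5.2, 3.9, 6.0],
            [4.0, 5.0, 4.2, 5.8],
            [7.3, 6.1, 7.0, 5.5],
            [7.1, 6.4, 6.8, 5.9],
            [5.5, 5.6, 5.4, 5.7],
            [3.2, 7.9, 2.8, 8.4],
        ]
    )
    return ExpressionMatrix(
        [f"g{i}" for i in range(6)], [f"s{j}" for j in range(4)], values
    )


@pytest.fixture(scope="session")
def default_synthetic():
    """The default test-suite dataset (300x6, 3 clusters, 10% DE)."""
    return generate_complete(SyntheticSpec(seed=7))


def make_masked(matrix: ExpressionMatrix, cells: list[tuple[int, int]]) -> MaskedMatrix:
    """MaskedMatrix hiding exactly the given (row, col) cells."""
    mask = np.zeros(matrix.shape, dtype=bool)
    for g, c in cells:
        mask[g, c] = True
    pct = mask.sum() / mask.size
    return MaskedMatrix(matrix, mask, pct)


@pytest.fixture()
def zero_plugin(tmp_path):
    """An external plugin executable that fills NA cells with 0."""
    script = tmp_path / "zero_plugin.py"
    script.write_text(
        textwrap.dedent(
            """\
            import sys

            src, dst = sys.argv[1], sys.argv[2]
            lines = open(src).read().splitlines()
            out = [lines[0]]
            for line in lines[1:]:
                parts = line.split("\\t")
                parts = [p if p.strip() != "NA" else "0.0" for p in parts]
                out.append("\\t".join(parts))
            open(dst, "w").write("\\n".join(out) + "\\n")
            """
        )
    )
    from imputebench import PluginContract

    return PluginContract("zerocopy", sys.executable, (str(script),), timeout=120)
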