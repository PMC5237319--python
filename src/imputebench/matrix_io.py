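"""Reading, validating and writing expression matrices in flat TSV form.

The on-disk format is a tab-separated table: first header cell ``gene_id``,
remaining header cells the sample IDs, one row per gene.  Missing entries are
written as ``NA`` and accepted on input as ``NA``, ``NaN`` or an empty field
(case-insensitive).  Group labels for two-group differential-expression
testing live in a sidecar two-column TSV (``sample_id<TAB>group``), never in
the matrix header.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "MaskedMatrix",
    "ImputationResult",
    "MatrixValidationError",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "read_group_labels",
    "write_group_labels",
]

#: tokens accepted as missing on input (compared case-insensitively)
MISSING_TOKENS = {"na", "nan", ""}
#: token always used for missing values on output
MISSING_OUT = "NA"


class MatrixValidationError(ValueError):
    """An expression matrix violates a structural invariant."""


class MatrixParseError(ValueError):
    """A matrix file could not be parsed; message names the offending cell."""


@dataclass
class ExpressionMatrix:
    """A genes x samples real matrix with row/column identifiers.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers.
    sample_ids : sequence of str
        Unique column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Log-scale expression values; ``NaN`` marks a missing entry.
    group_labels : sequence of str, optional
        Per-sample two-level group assignment used by the differential-
        expression index.  ``None`` means "no labels supplied".
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise MatrixValidationError("values must be a 2-D matrix")
        n, s = self.values.shape
        if n == 0 or s == 0:
            raise MatrixValidationError("matrix must have at least one gene and one sample")
        if n != len(self.gene_ids):
            raise MatrixValidationError(
                f"row count {n} != number of gene IDs {len(self.gene_ids)}"
            )
        if s != len(self.sample_ids):
            raise MatrixValidationError(
                f"column count {s} != number of sample IDs {len(self.sample_ids)}"
            )
        if len(set(self.gene_ids)) != n:
            raise MatrixValidationError("duplicate gene IDs")
        if len(set(self.sample_ids)) != s:
            raise MatrixValidationError("duplicate sample IDs")
        if np.isinf(self.values).any():
            raise MatrixValidationError("matrix contains non-finite (inf) values")
        if self.group_labels is not None:
            self.group_labels = [str(g) for g in self.group_labels]
            if len(self.group_labels) != s:
                raise MatrixValidationError("one group label per sample required")

    # -- basic queries ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    @property
    def is_complete(self) -> bool:
        """True when the matrix has no missing entries."""
        return self.n_missing == 0

    def require_complete(self) -> None:
        if not self.is_complete:
            raise MatrixValidationError(
                f"matrix is not complete: {self.n_missing} missing entries"
            )

    def with_groups(self, labels: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy with group labels attached."""
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids), self.values.copy(), list(labels)
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids),
            list(self.sample_ids),
            self.values.copy(),
            None if self.group_labels is None else list(self.group_labels),
        )


@dataclass
class MaskedMatrix:
    """A complete matrix with an MCAR mask applied at a nominal percentage.

    ``mask`` is True at entries hidden from the imputer.  ``values`` exposes
    the testing matrix (NaN at masked cells); the ground truth stays in
    ``base``.
    """

    base: ExpressionMatrix
    mask: np.ndarray
    percentage: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.base.shape:
            raise MatrixValidationError("mask shape must match matrix shape")
        self.base.require_complete()
        obs = ~self.mask
        if (obs.sum(axis=1) < 2).any():
            raise MatrixValidationError("every gene must retain >= 2 observed entries")
        if (obs.sum(axis=0) < 1).any():
            raise MatrixValidationError("every sample must retain >= 1 observed entry")

    @property
    def values(self) -> np.ndarray:
        """Testing matrix: base values with NaN at masked cells."""
        v = self.base.values.copy()
        v[self.mask] = np.nan
        return v

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def as_matrix(self) -> ExpressionMatrix:
        """The testing matrix as an (incomplete) ExpressionMatrix."""
        return ExpressionMatrix(
            list(self.base.gene_ids),
            list(self.base.sample_ids),
            self.values,
            None if self.base.group_labels is None else list(self.base.group_labels),
        )

    def mask_pairs(self) -> list[tuple[str, str]]:
        """Masked cells as (gene_id, sample_id) pairs, row-major, for audit."""
        gi, si = np.nonzero(self.mask)
        return [(self.base.gene_ids[g], self.base.sample_ids[s]) for g, s in zip(gi, si)]


@dataclass
class ImputationResult:
    """A completed matrix produced by one algorithm on one masked matrix."""

    algorithm_id: str
    source: MaskedMatrix
    imputed: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.imputed = np.asarray(self.imputed, dtype=np.float64)
        if self.imputed.shape != self.source.base.shape:
            raise MatrixValidationError("imputed matrix shape must match source")
        if np.isnan(self.imputed).any():
            raise MatrixValidationError("imputed matrix still contains missing entries")
        obs = ~self.source.mask
        if not np.array_equal(self.imputed[obs], self.source.base.values[obs]):
            raise MatrixValidationError("observed entries were altered by imputation")

    def as_matrix(self) -> ExpressionMatrix:
        base = self.source.base
        return ExpressionMatrix(
            list(base.gene_ids),
            list(base.sample_ids),
            self.imputed.copy(),
            None if base.group_labels is None else list(base.group_labels),
        )


def _parse_cell(token: str, row_id: str, col_id: str) -> float:
    if token.strip().lower() in MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise MatrixParseError(
            f"non-numeric value {token!r} at gene {row_id!r}, sample {col_id!r}"
        ) from None


def read_matrix(
    path: Union[str, Path],
    delimiter: str = "\t",
    group_labels_path: Optional[Union[str, Path]] = None,
) -> ExpressionMatrix:
    """Read an expression matrix from a delimited text file.

    The first column holds gene IDs, the first row sample IDs.  Missing
    entries may be ``NA``, ``NaN`` or empty.  Raises
    :class:`MatrixParseError` for ragged rows or non-numeric cells and
    :class:`MatrixValidationError` for duplicate identifiers.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise MatrixParseError(f"{path}: empty file") from None
        if len(header) < 2:
            raise MatrixParseError(f"{path}: header must contain at least one sample ID")
        sample_ids = [h.strip() for h in header[1:]]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue  # ignore trailing blank lines
            if len(row) != len(header):
                raise MatrixParseError(
                    f"{path}:{lineno}: ragged row ({len(row)} fields, expected {len(header)})"
                )
            gid = row[0].strip()
            gene_ids.append(gid)
            rows.append([_parse_cell(tok, gid, sid) for tok, sid in zip(row[1:], sample_ids)])
    if not rows:
        raise MatrixParseError(f"{path}: no data rows")
    matrix = ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=np.float64))
    if group_labels_path is not None:
        labels = read_group_labels(group_labels_path)
        try:
            matrix = matrix.with_groups([labels[s] for s in sample_ids])
        except KeyError as exc:
            raise MatrixValidationError(f"group-label file missing sample {exc}") from None
    return matrix


def write_matrix(
    m: Union[ExpressionMatrix, MaskedMatrix, ImputationResult],
    path: Union[str, Path],
) -> Path:
    """Write a matrix as TSV with ``NA`` for missing entries.

    Accepts an :class:`ExpressionMatrix`, a :class:`MaskedMatrix` (the
    testing-matrix view is written) or an :class:`ImputationResult`.
    ``read_matrix(write_matrix(m))`` reproduces ``m`` to text round-trip
    precision; finite values use ``repr`` so the round trip is exact.
    """
    if isinstance(m, (MaskedMatrix, ImputationResult)):
        m = m.as_matrix()
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        for gid, row in zip(m.gene_ids, m.values):
            cells = [MISSING_OUT if math.isnan(v) else repr(float(v)) for v in row]
            fh.write(gid + "\t" + "\t".join(cells) + "\n")
    return path


def read_group_labels(path: Union[str, Path], delimiter: str = "\t") -> dict[str, str]:
    """Read a sidecar two-column (sample_id, group) label file."""
    labels: dict[str, str] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise MatrixParseError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            sid, grp = row[0].strip(), row[1].strip()
            if sid.lower() == "sample_id":  # optional header
                continue
            if sid in labels:
                raise MatrixValidationError(f"duplicate sample {sid!r} in label file")
            labels[sid] = grp
    if not labels:
        raise MatrixParseError(f"{path}: no labels found")
    return labels


def write_group_labels(matrix: ExpressionMatrix, path: Union[str, Path]) -> Path:
    if matrix.group_labels is None:
        raise MatrixValidationError("matrix has no group labels to write")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, grp in zip(matrix.sample_ids, matrix.group_labels):
            fh.write(f"{sid}\t{grp}\n")
    return path
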