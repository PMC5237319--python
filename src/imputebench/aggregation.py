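"""Comprehensive performance scores: ORS (rank sums) and ONS (normalised sums).

Within every (index, dataset) cell the algorithms are ranked by their final
score (rank 1 = best; ties get fractional average ranks).  ORS(k) is the
sum of algorithm k's ranks over all cells — smaller is better.  ONS(k) sums
the normalised scores ``N_ij(k) = S_ij(k) / max_k' S_ij(k')`` — larger is
better, with maximum I*J attained only by an algorithm that is best in
every cell.  Because BLCI can be negative while the normalisation assumes
non-negative scores, BLCI cells are affinely mapped from [-1, 1] to [0, 1]
before normalising (recorded in the report).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .evaluation import ScoreTable

__all__ = ["RankTable", "compute_ors", "compute_ons", "compute_ranks", "render_report"]


class AggregationError(ValueError):
    """Comprehensive scores are undefined on the given table."""


@dataclass
class RankTable:
    """Per-cell ranks, normalised scores and the two comprehensive sums."""

    index_ids: list[str]
    dataset_ids: list[str]
    algorithm_ids: list[str]
    ranking: np.ndarray                 # (I, J, m) fractional ranks, NaN for failed
    N: np.ndarray                       # (I, J, m) normalised scores, NaN for failed
    ORS: np.ndarray                     # (m,)
    ONS: np.ndarray                     # (m,)
    evaluated_cells: np.ndarray         # (m,) cells each algorithm was ranked in
    notes: list[str] = field(default_factory=list)

    def overall_frame(self, score: str = "ors") -> pd.DataFrame:
        """Overall ranking table sorted by the chosen comprehensive score."""
        df = pd.DataFrame(
            {
                "algorithm": self.algorithm_ids,
                "ORS": self.ORS,
                "ONS": self.ONS,
                "evaluated_cells": self.evaluated_cells,
            }
        )
        if score == "ors":
            df = df.sort_values("ORS", ascending=True, kind="mergesort")  # small = good
        elif score == "ons":
            df = df.sort_values("ONS", ascending=False, kind="mergesort")  # large = good
        else:
            raise ValueError(f"unknown comprehensive score {score!r}")
        df.insert(0, "overall_rank", np.arange(1, len(df) + 1))
        return df.reset_index(drop=True)


def _check_cells(table: ScoreTable) -> np.ndarray:
    """Valid-score mask; warn about dropped cells, error on empty scope."""
    valid = ~np.isnan(table.S)
    dead = (~valid).all(axis=2)
    if dead.any():
        warnings.warn(f"{int(dead.sum())} cell(s) have no surviving algorithm and are dropped")
    if valid.sum() == 0:
        raise AggregationError("no evaluated cells: every algorithm failed everywhere")
    return valid


def compute_ranks(table: ScoreTable) -> np.ndarray:
    """Within-cell fractional ranks (1 = best, descending score order)."""
    valid = _check_cells(table)
    I, J, m = table.S.shape
    ranking = np.full((I, J, m), np.nan)
    for i in range(I):
        for j in range(J):
            ok = valid[i, j]
            if ok.sum() == 0:
                continue
            ranking[i, j, ok] = rankdata(-table.S[i, j, ok], method="average")
    return ranking


def compute_ors(table: ScoreTable, ranking: Optional[np.ndarray] = None) -> np.ndarray:
    """Overall ranking score per algorithm (sum of within-cell ranks)."""
    if ranking is None:
        ranking = compute_ranks(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nansum(ranking, axis=(0, 1))


def compute_ons(table: ScoreTable) -> tuple[np.ndarray, np.ndarray]:
    """Normalised scores N_ij(k) and their per-algorithm sums ONS(k).

    BLCI rows are mapped (value + 1) / 2 before normalising so every score
    is non-negative and 0 <= N_ij(k) <= 1 holds as the definition assumes.
    """
    valid = _check_cells(table)
    S = table.S.copy()
    for i, idx in enumerate(table.index_ids):
        if idx == "blci":
            S[i] = (S[i] + 1.0) / 2.0
    I, J, m = S.shape
    N = np.full((I, J, m), np.nan)
    for i in range(I):
        for j in range(J):
            ok = valid[i, j]
            if ok.sum() == 0:
                continue
            top = np.max(S[i, j, ok])
            if top <= 0:
                raise AggregationError(
                    f"cell (index={table.index_ids[i]}, dataset={table.dataset_ids[j]}) "
                    "has non-positive maximum score; ONS undefined"
                )
            N[i, j, ok] = S[i, j, ok] / top
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ons = np.nansum(N, axis=(0, 1))
    return N, ons


def aggregate(table: ScoreTable) -> RankTable:
    """Compute ranks, ORS, normalised scores and ONS in one pass."""
    ranking = compute_ranks(table)
    ors = compute_ors(table, ranking)
    N, ons = compute_ons(table)
    notes = []
    if "blci" in table.index_ids:
        notes.append("BLCI scores were mapped (value+1)/2 to [0,1] before ONS normalisation")
    return RankTable(
        list(table.index_ids),
        list(table.dataset_ids),
        list(table.algorithm_ids),
        ranking,
        N,
        ors,
        ons,
        np.sum(~np.isnan(ranking), axis=(0, 1)),
        notes,
    )


def render_report(
    table: ScoreTable,
    ranks: Optional[RankTable] = None,
    outdir: Union[str, Path] = "report",
    indices: Optional[Sequence[str]] = None,
    datasets: Optional[Sequence[str]] = None,
    figures: bool = False,
) -> dict[str, Path]:
    """Write ranked comparison reports (TSV tables, summary JSON, optional figures).

    ``indices``/``datasets`` restrict the scope (the aggregation is then
    recomputed on the sub-table); both overall orderings (by ORS and by
    ONS) are written even when they disagree.
    """
    sub = _subset(table, indices, datasets)
    if ranks is None or sub is not table:
        ranks = aggregate(sub)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    for score in ("ors", "ons"):
        path = outdir / f"overall_{score}.tsv"
        ranks.overall_frame(score).to_csv(path, sep="\t", index=False)
        written[f"overall_{score}"] = path

    for i, idx in enumerate(sub.index_ids):
        for j, ds in enumerate(sub.dataset_ids):
            detail = pd.DataFrame(
                {
                    "algorithm": sub.algorithm_ids,
                    "S": sub.S[i, j],
                    "rank": ranks.ranking[i, j],
                    "N": ranks.N[i, j],
                }
            ).sort_values("rank", kind="mergesort").reset_index(drop=True)
            path = outdir / f"detail_{idx}_{ds}.tsv"
            detail.to_csv(path, sep="\t", index=False)
            written[f"detail_{idx}_{ds}"] = path

    summary = {
        "index_ids": sub.index_ids,
        "dataset_ids": sub.dataset_ids,
        "algorithm_ids": sub.algorithm_ids,
        "percentages": list(sub.percentages),
        "B": sub.B,
        "S": _nan_to_none(sub.S),
        "N": _nan_to_none(ranks.N),
        "ranking": _nan_to_none(ranks.ranking),
        "ORS": ranks.ORS.tolist(),
        "ONS": ranks.ONS.tolist(),
        "evaluated_cells": ranks.evaluated_cells.tolist(),
        "notes": ranks.notes,
    }
    spath = outdir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    written["summary"] = spath

    if figures:
        written.update(_bar_charts(sub, ranks, outdir))
    return written


def _subset(table: ScoreTable, indices, datasets) -> ScoreTable:
    if indices is None and datasets is None:
        return table
    i_sel = [table.index_ids.index(i) for i in (indices or table.index_ids)]
    j_sel = [table.dataset_ids.index(d) for d in (datasets or table.dataset_ids)]
    if not i_sel or not j_sel:
        raise AggregationError("empty report scope")
    return ScoreTable(
        [table.index_ids[i] for i in i_sel],
        [table.dataset_ids[j] for j in j_sel],
        list(table.algorithm_ids),
        table.percentages,
        table.S[np.ix_(i_sel, j_sel)],
        table.raw[np.ix_(i_sel, j_sel)],
        table.failed[j_sel],
        table.mask_checksums,
    )


def _nan_to_none(a: np.ndarray):
    """JSON-friendly nested lists with NaN replaced by null."""
    return np.where(np.isnan(a), None, a.astype(object)).tolist()


def _bar_charts(table: ScoreTable, ranks: RankTable, outdir: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    for i, idx in enumerate(table.index_ids):
        for j, ds in enumerate(table.dataset_ids):
            fig, ax = plt.subplots(figsize=(8, 4))
            ax.bar(table.algorithm_ids, table.S[i, j])
            ax.set_ylabel(f"{idx} score")
            ax.set_title(f"{idx} on {ds}")
            ax.tick_params(axis="x", rotation=75)
            fig.tight_layout()
            path = outdir / f"figure_{idx}_{ds}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written[f"figure_{idx}_{ds}"] = path
    return written
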