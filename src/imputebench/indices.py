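"""The three performance indices: 1/NRMSE, CPP and BLCI.

Each index compares an imputed matrix against the original complete matrix
and is oriented so that higher is better.  1/NRMSE measures numerical
similarity at the masked cells; CPP (cluster pair proportion) measures how
well gene clustering survives imputation; BLCI (biomarker list concordance
index) measures how well two-group differential-expression calls survive
imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .matrix_io import ExpressionMatrix, ImputationResult, MaskedMatrix

__all__ = [
    "IndexScore",
    "IndexError_",
    "INDEX_IDS",
    "inv_nrmse",
    "cpp",
    "blci",
    "compute_index",
    "default_groups",
]

INDEX_IDS = ("inv_nrmse", "cpp", "blci")

#: 1/NRMSE is reported as this cap when NRMSE underflows (perfect imputation)
INV_NRMSE_CAP = 1e12


class IndexError_(ValueError):
    """A performance index is undefined on the given inputs."""


@dataclass
class IndexScore:
    index_id: str
    value: float
    components: dict = field(default_factory=dict)


def _imputed_values(result: Union[ImputationResult, np.ndarray]) -> np.ndarray:
    if isinstance(result, ImputationResult):
        return result.imputed
    return np.asarray(result, dtype=np.float64)


def inv_nrmse(
    complete: ExpressionMatrix,
    result: Union[ImputationResult, np.ndarray],
    mask: Union[MaskedMatrix, np.ndarray],
    normalization: str = "sd",
) -> IndexScore:
    """Inverse normalised root-mean-square error at the masked cells.

    ``NRMSE = sqrt(mean((imputed - true)^2)) / norm`` where ``norm`` is the
    population SD of the true values at the masked cells (``"sd"``, the
    local-least-squares literature convention) or the mean of those values
    (``"mean"``).  The score is ``1/NRMSE``, capped at 1e12 for
    numerically perfect imputation, and invariant under affine rescaling of
    both matrices under the "sd" normalisation.
    """
    m = mask.mask if isinstance(mask, MaskedMatrix) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise IndexError_("1/NRMSE undefined on an empty mask")
    true = complete.values[m]
    imp = _imputed_values(result)[m]
    if normalization == "sd":
        norm = float(true.std())  # population SD
    elif normalization == "mean":
        norm = float(np.abs(true.mean()))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if norm < 1e-300:
        raise IndexError_(
            "degenerate mask: true values at masked cells have zero "
            f"{'spread' if normalization == 'sd' else 'mean'}"
        )
    nrmse = float(np.sqrt(np.mean((imp - true) ** 2))) / norm
    value = INV_NRMSE_CAP if nrmse < 1e-12 else min(1.0 / nrmse, INV_NRMSE_CAP)
    return IndexScore("inv_nrmse", value, {"nrmse": nrmse, "n_masked": int(m.sum())})


def _copair_counts(labels_a: np.ndarray, labels_b: np.ndarray) -> tuple[int, int]:
    """(pairs co-clustered in a AND b, pairs co-clustered in a) via contingency."""
    a_ids, a_inv = np.unique(labels_a, return_inverse=True)
    b_ids, b_inv = np.unique(labels_b, return_inverse=True)
    cont = np.zeros((a_ids.size, b_ids.size), dtype=np.int64)
    np.add.at(cont, (a_inv, b_inv), 1)
    pairs_a = int(sum(n * (n - 1) // 2 for n in cont.sum(axis=1)))
    pairs_both = int((cont * (cont - 1) // 2).sum())
    return pairs_both, pairs_a


def cpp(
    complete: ExpressionMatrix,
    result: Union[ImputationResult, np.ndarray],
    k_clusters: int = 10,
    seed: int = 0,
    n_init: int = 10,
) -> IndexScore:
    """Cluster pair proportion.

    Genes of the complete and of the imputed matrix are clustered
    separately with k-means (same k, same seed, best of ``n_init``
    restarts); the score is the fraction of gene pairs co-clustered in the
    complete clustering that remain co-clustered in the imputed one.
    """
    if k_clusters < 2:
        raise ValueError("k_clusters must be >= 2")
    if complete.n_genes < k_clusters:
        raise IndexError_("fewer genes than clusters")
    imp = _imputed_values(result)
    km = lambda V: KMeans(n_clusters=k_clusters, n_init=n_init, random_state=seed).fit_predict(V)
    labels_c = km(complete.values)
    labels_i = km(imp)
    preserved, total = _copair_counts(labels_c, labels_i)
    if total == 0:
        raise IndexError_("no co-clustered pairs in the complete matrix (all singletons)")
    return IndexScore(
        "cpp",
        preserved / total,
        {"pairs_complete": total, "pairs_preserved": preserved, "k": k_clusters},
    )


def default_groups(n_samples: int) -> list[str]:
    """First-half vs second-half grouping used when no labels are supplied.

    Time-series matrices have no natural two-group split; this deterministic
    default (early vs late samples) is applied and should be flagged to the
    user in reports.
    """
    half = n_samples // 2
    return ["A"] * half + ["B"] * (n_samples - half)


def _de_calls(values: np.ndarray, groups: np.ndarray, alpha: float) -> np.ndarray:
    import warnings

    g1 = values[:, groups == np.unique(groups)[0]]
    g2 = values[:, groups == np.unique(groups)[1]]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant genes trigger a precision warning and a NaN p-value; such
        # genes are simply never called significant
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(g1, g2, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    return p < alpha


def blci(
    complete: ExpressionMatrix,
    result: Union[ImputationResult, np.ndarray],
    groups: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> IndexScore:
    """Biomarker list concordance index.

    With ``D_o`` the genes called differentially expressed (Welch two-sample
    t-test, p < alpha, no multiplicity correction) on the complete matrix
    and ``D_i`` the same on the imputed matrix::

        BLCI = |D_o & D_i| / |D_o| + |~D_o & ~D_i| / |~D_o| - 1

    ranging from -1 (perfect discordance) to 1 (perfect concordance).
    Groups default to the matrix's attached labels, else to a first-half /
    second-half split of the samples.
    """
    if groups is None:
        groups = complete.group_labels or default_groups(complete.n_samples)
    groups = np.asarray([str(g) for g in groups])
    levels = np.unique(groups)
    if levels.size != 2:
        raise IndexError_(f"need exactly 2 groups, got {levels.size}")
    if min((groups == lv).sum() for lv in levels) < 2:
        raise IndexError_("each group needs >= 2 samples for a t-test")
    d_o = _de_calls(complete.values, groups, alpha)
    d_i = _de_calls(_imputed_values(result), groups, alpha)
    n_o = int(d_o.sum())
    if n_o == 0 or n_o == d_o.size:
        raise IndexError_(
            f"degenerate DE set on the complete matrix ({n_o} of {d_o.size} genes "
            "significant); adjust alpha or the synthetic effect size"
        )
    tp = int((d_o & d_i).sum())
    tn = int((~d_o & ~d_i).sum())
    value = tp / n_o + tn / (d_o.size - n_o) - 1.0
    return IndexScore(
        "blci",
        value,
        {"n_de_complete": n_o, "n_de_imputed": int(d_i.sum()), "tp": tp, "tn": tn},
    )


def compute_index(
    index_id: str,
    complete: ExpressionMatrix,
    result: Union[ImputationResult, np.ndarray],
    mask: Union[MaskedMatrix, np.ndarray, None] = None,
    **params,
) -> IndexScore:
    """Dispatch on index id with that index's keyword parameters."""
    if index_id == "inv_nrmse":
        if mask is None:
            raise ValueError("inv_nrmse requires the mask")
        return inv_nrmse(complete, result, mask, **params)
    if index_id == "cpp":
        return cpp(complete, result, **params)
    if index_id == "blci":
        return blci(complete, result, **params)
    raise ValueError(f"unknown index {index_id!r}; known: {', '.join(INDEX_IDS)}")
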