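"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives an operation from its documented contract with the
most naive approach available (cell-by-cell loops, explicit pair
enumeration, explicit normal equations) and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

EPS = 1e-12


def knn_oracle(X: np.ndarray, k: int) -> np.ndarray:
    """Brute-force gene-wise KNN imputation.

    Candidates for a target gene are genes observed at all of the target's
    missing columns; distance is the RMS difference over jointly observed
    columns; each missing cell is the inverse-distance-weighted mean of the
    k nearest candidates' values in that column, ties broken by ascending
    row index.  Cells with no candidate fall back to the row average.
    """
    X = np.asarray(X, dtype=float)
    out = X.copy()
    n, s = X.shape
    for g in range(n):
        miss = [c for c in range(s) if np.isnan(X[g, c])]
        if not miss:
            continue
        cands = []
        for h in range(n):
            if h == g:
                continue
            if any(np.isnan(X[h, c]) for c in miss):
                continue
            shared = [c for c in range(s) if not np.isnan(X[g, c]) and not np.isnan(X[h, c])]
            if not shared:
                continue
            d = np.sqrt(np.mean([(X[g, c] - X[h, c]) ** 2 for c in shared]))
            cands.append((d, h))
        if not cands:
            obs_vals = [X[g, c] for c in range(s) if not np.isnan(X[g, c])]
            for c in miss:
                out[g, c] = np.mean(obs_vals)
            continue
        cands.sort()  # (distance, row index): exactly the documented tie-break
        top = cands[:k]
        for c in miss:
            wsum = sum(1.0 / (d + EPS) for d, _ in top)
            out[g, c] = sum((1.0 / (d + EPS)) * X[h, c] for d, h in top) / wsum
    return out


def ls_oracle(X: np.ndarray, k: int, eps: float = 1e-6) -> np.ndarray:
    """Brute-force correlation-weighted regression imputation.

    For each missing cell: candidates observed in that column with >= 3
    columns jointly observed with the target and non-degenerate variance;
    the k most |r|-correlated (ties by row index) each give a simple
    least-squares prediction, combined with weights (r^2/(1-r^2+eps))^2.
    """
    X = np.asarray(X, dtype=float)
    out = X.copy()
    n, s = X.shape
    for g in range(n):
        for c in range(s):
            if not np.isnan(X[g, c]):
                continue
            cands = []
            for h in range(n):
                if h == g or np.isnan(X[h, c]):
                    continue
                shared = [
                    t for t in range(s) if not np.isnan(X[g, t]) and not np.isnan(X[h, t])
                ]
                if len(shared) < 3:
                    continue
                x = np.array([X[h, t] for t in shared])
                y = np.array([X[g, t] for t in shared])
                if x.std() < 1e-10 or y.std() < 1e-10:
                    continue
                r = float(np.corrcoef(x, y)[0, 1])
                b = r * y.std() / x.std()
                a = float(y.mean() - b * x.mean())
                cands.append((-abs(r), h, a, b, r))
            if not cands:
                obs_vals = [X[g, t] for t in range(s) if not np.isnan(X[g, t])]
                out[g, c] = np.mean(obs_vals)
                continue
            cands.sort()
            top = cands[:k]
            ws, ps = [], []
            for negr, h, a, b, r in top:
                ws.append((r**2 / (1 - r**2 + eps)) ** 2)
                ps.append(a + b * X[h, c])
            ws = np.array(ws)
            if ws.sum() < 1e-300:
                ws = np.ones_like(ws)
            out[g, c] = float(np.dot(ws, ps) / ws.sum())
    return out


def lls_oracle(X: np.ndarray, k: int) -> np.ndarray:
    """Brute-force local least squares via explicit pseudoinverse.

    Neighbours are fully complete genes; the k nearest by Euclidean
    distance on the target's observed columns (ties by row index) form the
    regression block A; the coefficient vector is the minimum-norm solution
    of w A_obs = target_obs computed with an explicit pseudoinverse.
    """
    X = np.asarray(X, dtype=float)
    out = X.copy()
    n, s = X.shape
    complete = [h for h in range(n) if not np.isnan(X[h]).any()]
    for g in range(n):
        miss = [c for c in range(s) if np.isnan(X[g, c])]
        if not miss:
            continue
        obs = [c for c in range(s) if not np.isnan(X[g, c])]
        cands = [h for h in complete if h != g]
        if not cands:
            for c in miss:
                out[g, c] = np.mean([X[g, t] for t in obs])
            continue
        dists = [
            (np.sqrt(sum((X[g, t] - X[h, t]) ** 2 for t in obs)), h) for h in cands
        ]
        dists.sort()
        sel = [h for _, h in dists[:k]]
        A = X[np.ix_(sel, obs)]           # (k, |obs|)
        bvec = X[g, obs]
        w = bvec @ np.linalg.pinv(A)      # min-norm least-squares coefficients
        for c in miss:
            out[g, c] = float(w @ X[sel, c])
    return out


def inv_nrmse_oracle(true_vals: np.ndarray, imp_vals: np.ndarray) -> float:
    """1/NRMSE from the definition, normalised by the population SD."""
    err = np.sqrt(np.mean((np.asarray(imp_vals) - np.asarray(true_vals)) ** 2))
    sd = np.std(np.asarray(true_vals))
    nrmse = err / sd
    return 1e12 if nrmse < 1e-12 else min(1.0 / nrmse, 1e12)


def cpp_pairs_oracle(labels_complete, labels_imputed) -> float:
    """CPP by explicit enumeration of all unordered gene pairs."""
    n = len(labels_complete)
    both = 0
    in_complete = 0
    for a, b in itertools.combinations(range(n), 2):
        if labels_complete[a] == labels_complete[b]:
            in_complete += 1
            if labels_imputed[a] == labels_imputed[b]:
                both += 1
    return both / in_complete


def blci_oracle(d_o: set, d_i: set, all_genes: set) -> float:
    """BLCI from explicit set arithmetic."""
    comp_o = all_genes - d_o
    comp_i = all_genes - d_i
    return len(d_o & d_i) / len(d_o) + len(comp_o & comp_i) / len(comp_o) - 1.0


def fractional_ranks_oracle(scores) -> list[float]:
    """Average ranks (1 = best = largest score) by pairwise comparison."""
    ranks = []
    for s in scores:
        greater = sum(1 for t in scores if t > s)
        equal = sum(1 for t in scores if t == s)
        ranks.append(greater + (equal + 1) / 2)
    return ranks


def ons_oracle(S: np.ndarray) -> np.ndarray:
    """ONS(k) by direct evaluation of the normalised-score sum."""
    S = np.asarray(S, dtype=float)
    I, J, m = S.shape
    ons = np.zeros(m)
    for k in range(m):
        for i in range(I):
            for j in range(J):
                ons[k] += S[i, j, k] / max(S[i, j, kk] for kk in range(m))
    return ons


def valid_masks(n: int, s: int, n_cells_masked: int):
    """All masks of the given size keeping >=2 observed per row, >=1 per column."""
    for cells in itertools.combinations(range(n * s), n_cells_masked):
        mask = np.zeros((n, s), dtype=bool)
        for cell in cells:
            mask[cell // s, cell % s] = True
        obs = ~mask
        if (obs.sum(axis=1) >= 2).all() and (obs.sum(axis=0) >= 1).all():
            yield mask
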