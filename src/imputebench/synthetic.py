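"""Synthetic complete expression matrices with planted structure.

The generator emulates the structure of small two-condition microarray
studies (hundreds to thousands of genes, 6-10 samples): genes fall into a
few co-expressed clusters, a fraction of genes is differentially expressed
between two equal sample groups, and iid Gaussian noise is added on top.
Because the cluster partition and the DE gene set are planted, every
performance index (1/NRMSE, CPP, BLCI) has recoverable ground truth without
any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .matrix_io import ExpressionMatrix

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_complete", "generate_timecourse"]

#: common scale of the varying part of each cluster profile
PROFILE_NORM = 3.0
#: baseline log-intensity of the first cluster; clusters are offset by 1 each
BASELINE = 6.0


class SyntheticSpecError(ValueError):
    """Invalid synthetic-data specification."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults are the test-suite workhorse: 300 genes x 6 samples, 3 clusters,
    10% DE genes with a 2.5-SD shift and noise SD 0.5 -- small enough that
    every imputer runs in well under a second.
    """

    n_genes: int = 300
    n_samples: int = 6
    n_clusters: int = 3
    de_fraction: float = 0.1
    effect_size: float = 2.5
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SyntheticSpecError("n_genes must be positive")
        if self.n_samples < 2 or self.n_samples % 2 != 0:
            raise SyntheticSpecError("n_samples must be a positive even integer (two equal groups)")
        if not (1 <= self.n_clusters <= self.n_genes):
            raise SyntheticSpecError("need 1 <= n_clusters <= n_genes")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise SyntheticSpecError("de_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise SyntheticSpecError("noise_sd must be non-negative")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated matrix."""

    cluster_assignment: np.ndarray  # (n_genes,) int cluster index per gene
    de_genes: list[str]             # gene IDs carrying the between-group shift
    spec: SyntheticSpec

    def to_json(self, path: Union[str, Path]) -> Path:
        payload = {
            "cluster_assignment": self.cluster_assignment.tolist(),
            "de_genes": list(self.de_genes),
            "spec": asdict(self.spec),
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        return path


def _cluster_sizes(n_genes: int, n_clusters: int) -> np.ndarray:
    """Near-equal sizes (differ by at most 1), larger clusters first."""
    base, extra = divmod(n_genes, n_clusters)
    return np.array([base + (1 if c < extra else 0) for c in range(n_clusters)])


def _flat_profiles(n_clusters: int, n_samples: int) -> np.ndarray:
    """Distinct deterministic cluster profiles for two-group replicate data.

    Each cluster sits at its own constant baseline expression level
    (BASELINE + cluster index, emulating the positive log-intensity scale
    of preprocessed microarray data), constant across samples.  Replicate
    samples within a condition must share the gene's expected value:
    any sample-varying pattern would inflate the within-group variance
    seen by the differential-expression t-test and confound the two-group
    comparison, destroying the planted DE truth.  With constant profiles
    the matrix rows are drawn from n_clusters fixed vectors, so the
    zero-noise rank stays exactly controlled (+1 once the DE shift is
    added) and k-means recovers the planted partition from the baseline
    separation alone.
    """
    levels = BASELINE + np.arange(n_clusters, dtype=float)
    return np.tile(levels[:, None], (1, n_samples))


def _smooth_profiles(n_clusters: int, n_samples: int) -> np.ndarray:
    """Smooth time-course profiles: tents and centred cosines.

    Alternating rise-then-fall tents and single-dip centred cosines at
    growing amplitude, each on its own baseline.  Both shapes vary slowly
    with the time index, so cluster means carry positive lag-1
    autocorrelation and neighbour-based imputers see genuine temporal
    correlation; both are symmetric about the midpoint of the series, so
    the default early-vs-late sample split used by the DE index stays
    balanced for non-DE genes.
    """
    t = np.arange(n_samples, dtype=float)
    centred = t - (n_samples - 1) / 2.0
    profiles = np.empty((n_clusters, n_samples))
    for c in range(n_clusters):
        if c % 2 == 0:
            raw = -np.abs(centred)           # tent: rise then fall
        else:
            raw = np.cos(2 * np.pi * centred / n_samples)
        raw = raw - raw.mean()
        scale = 1.0 + c // 2
        norm = np.linalg.norm(raw)
        profiles[c] = (BASELINE + c) + PROFILE_NORM * scale * raw / (norm if norm > 0 else 1.0)
    return profiles


def _assemble(spec: SyntheticSpec, profiles: np.ndarray) -> tuple[ExpressionMatrix, SyntheticTruth]:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = _cluster_sizes(spec.n_genes, spec.n_clusters)
    assignment = np.repeat(np.arange(spec.n_clusters), sizes)

    values = profiles[assignment].copy()

    # DE genes: evenly spread across clusters (round-robin over the cluster
    # blocks) so clustering truth and DE truth stay decoupled; the shift is
    # applied to group-2 samples only.
    n_de = int(np.floor(spec.de_fraction * spec.n_genes + 0.5))
    block_starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    de_idx: list[int] = []
    offset = 0
    while len(de_idx) < n_de:
        for c in range(spec.n_clusters):
            if len(de_idx) >= n_de:
                break
            if offset < sizes[c]:
                de_idx.append(int(block_starts[c] + offset))
        offset += 1
    de_idx = sorted(de_idx)

    half = spec.n_samples // 2
    group2 = np.arange(half, spec.n_samples)
    shift = spec.effect_size * spec.noise_sd
    for g in de_idx:
        values[g, group2] += shift

    values += rng.normal(0.0, spec.noise_sd, size=values.shape)

    gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]
    sample_ids = [f"s{j}" for j in range(spec.n_samples)]
    labels = ["A"] * half + ["B"] * half
    matrix = ExpressionMatrix(gene_ids, sample_ids, values, labels)
    truth = SyntheticTruth(assignment, [gene_ids[g] for g in de_idx], spec)
    return matrix, truth


def generate_complete(spec: Optional[SyntheticSpec] = None, **kwargs) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a complete non-time-series matrix with planted truth.

    Value model for gene ``g`` (cluster ``c``) in sample ``s`` (group ``r``)::

        value = profile_c[s] + de_shift(g, r) + Normal(0, noise_sd)

    where ``profile_c`` includes a cluster-specific baseline on a positive
    log-intensity scale and ``de_shift = effect_size * noise_sd`` on
    group-2 samples of the planted DE genes (0 elsewhere).  The same seed reproduces the matrix
    bit for bit.
    """
    spec = spec if spec is not None else SyntheticSpec(**kwargs)
    spec.validate()
    return _assemble(spec, _flat_profiles(spec.n_clusters, spec.n_samples))


def generate_timecourse(spec: Optional[SyntheticSpec] = None, **kwargs) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a complete time-course matrix (smooth cluster profiles)."""
    spec = spec if spec is not None else SyntheticSpec(**kwargs)
    spec.validate()
    return _assemble(spec, _smooth_profiles(spec.n_clusters, spec.n_samples))
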