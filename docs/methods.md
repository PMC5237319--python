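# Methods

This note documents the models and procedures implemented in imputebench,
the defaults chosen where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## The simulation procedure

A benchmark study starts from a *complete* matrix `X` (genes × samples,
log-scale expression, no missing entries). For each simulation run and
each missing percentage `p ∈ {0.01, 0.03, 0.05, 0.08, 0.10}`, exactly
`round(p · n_genes · n_samples)` cells (round half away from zero) are
hidden, drawn uniformly without replacement over *all* matrix cells — the
MCAR assumption: missingness is independent of observed and unobserved
values. The draw is repeated (up to 1000 times) until every gene retains
at least two observed entries and every sample at least one; distance and
regression steps of the imputers are undefined on fully missing rows, so
this floor is a well-posedness constraint, not a change of the missingness
model (at the supported percentages ≤ 10% a redraw is rare). Each
percentage is an independent draw; masks are not nested.

Each testing matrix is imputed by every selected algorithm and each imputed
matrix is scored by every selected index against the complete matrix; after
`B` runs the final score `S_ij(k)` is the arithmetic mean of the
`|percentages| · B` raw scores. By default all algorithms within one
(dataset, run, percentage) receive the *identical* mask (paired design),
which removes mask-to-mask variance from every between-algorithm
comparison; `paired_masks=False` (CLI `--unpaired`) restores fully
independent draws. Imputed matrices are computed once per (algorithm,
mask) and reused across the three indices, so the work performed is
`J · m · |percentages| · B` imputations, independent of the number of
indices.

All randomness derives from a single `master_seed` through
`numpy.random.SeedSequence` spawn keys `(dataset, run, percentage[,
algorithm])`, so studies are bit-reproducible across processes and
machines and partial reruns reproduce the same masks. Mask CRC32 checksums
are recorded in the run manifest for audit.

A failing algorithm (e.g. a crashing plugin) marks only its own
(dataset, algorithm) cells as failed; failed cells are excluded from both
ORS and ONS symmetrically, with per-algorithm evaluated-cell counts
reported, rather than being zero-filled — zero-filling would corrupt the
rankings of everyone else.

## Performance indices

**1/NRMSE.** `NRMSE = sqrt(mean((imputed − true)²)) / SD(true)` over the
masked cells only, with the population SD of the true masked values as the
normaliser (the convention of the local-least-squares imputation
literature); `normalization="mean"` switches to the data-mean convention.
The score is `1/NRMSE`, capped at `1e12` when NRMSE underflows, so perfect
imputation has a finite, comparable value in the rank/normalisation
arithmetic. Under SD normalisation the index is invariant to affine
rescaling of the data. A mask whose true values have zero spread makes the
index undefined and raises an error naming the dataset.

**CPP.** Genes of the complete and imputed matrices are clustered
separately with k-means (default k = 10, 10 restarts, best inertia), using
the *same* seed for both clusterings so the index is a deterministic
function of the two matrices. CPP is the fraction of gene pairs
co-clustered in the complete clustering that remain co-clustered in the
imputed clustering (denominator = pairs in the complete clustering);
pair counts are computed from the contingency table of the two labelings.
The index is invariant to cluster relabeling; it lies in [0, 1].

**BLCI.** Differential expression is called per gene by a Welch two-sample
t-test at `alpha = 0.05` without multiplicity correction — the simplest
published selection rule; the threshold is configurable, and concordance
indices compare two gene *lists*, so the rule matters less than using the
same rule on both matrices. With `D_o`/`D_i` the DE sets of the
complete/imputed matrices, `BLCI = |D_o∩D_i|/|D_o| + |D_o^c∩D_i^c|/|D_o^c|
− 1 ∈ [−1, 1]`. Matrices without group labels (time courses) default to a
first-half vs second-half sample split — a deterministic stand-in that is
flagged to users; supplying a label file overrides it. `D_o` empty or
equal to all genes makes the index undefined (error with guidance).

## Rank aggregation

Within each (index, dataset) cell algorithms are ranked by descending
`S_ij(k)` (all indices are higher-is-better); ties receive fractional
average ranks, which preserves the rank-sum invariant
`Σ_k ORS(k) = C · m(m+1)/2` over `C` cells. `ONS(k) = Σ_ij S_ij(k) /
max_k' S_ij(k')`. Because BLCI can be negative while the normalised score
is defined on non-negative values (`0 ≤ N_ij(k) ≤ 1`), BLCI cells are
affinely mapped `(value+1)/2` onto [0, 1] before normalising — the mapping
is order-preserving, applies to all algorithms alike, and is recorded in
the report. ORS- and ONS-sorted reports can legitimately disagree; both
are always written, without reconciliation.

## Imputation algorithms

All imputers share one contract: input is a genes × samples matrix with
NaN at missing cells; output is complete; observed cells are preserved
bit-exactly (enforced centrally by overwriting observed cells after the
algorithm returns, making the invariant algorithm-independent);
neighbour/candidate ties are broken by ascending row index so every
algorithm is deterministic given its inputs and seed.

- **zero / row_average** — the naive baselines: 0, or the mean of the
  gene's observed values.
- **KNN** — candidates for a target gene are genes observed at all the
  target's missing samples; distance is RMS difference over jointly
  observed samples (normalised by the overlap size so candidates with
  different overlaps are comparable); a missing cell is the
  inverse-distance-weighted mean of the k (default 10) nearest candidates'
  values in that sample. Cells with no candidate fall back to the row
  average and are counted in diagnostics.
- **SKNN** — genes imputed in ascending missing-count order; completed
  genes join the candidate pool.
- **IKNN** — row-average start, then repeated complete-matrix KNN
  re-estimation of the originally missing cells until the maximum relative
  change falls below `tol` (1e-4) or `max_iter` (100).
- **SVD** — EM-style iterative truncated SVD: missing cells are repeatedly
  replaced by the rank-`r` reconstruction (default `r = max(1,
  round(0.2·n_samples))`) until the missing-cell change stabilises. Exact
  on rank-r data with matching rank.
- **BPCA** — variational EM for a probabilistic PCA model `x = Wz + μ + ε`
  over genes as data points, with per-factor automatic-relevance
  priors that shrink irrelevant factors (default `q = n_samples − 1`);
  missing entries are re-estimated each sweep from the posterior
  predictive mean given the row's observed part. Non-convergence returns
  the best iterate and is flagged in diagnostics.
- **LS** — per missing cell, the k (default 10) genes most
  |r|-correlated with the target over ≥ 3 jointly observed samples and
  observed in the missing sample each give a simple regression prediction;
  predictions are combined with weights `(r²/(1−r²+ε))²` normalised to
  sum 1.
- **LLS family** — the target's observed part is regressed on the
  corresponding parts of its k nearest *complete* genes (minimum-norm
  least squares via `lstsq`; rank-deficient blocks fall back to the
  pseudoinverse solution and are flagged); the same coefficients combine
  the neighbours' values at the missing samples. Default
  `k = clip(round(0.1·n_genes), 5, 150)`, reduced with a diagnostic when
  fewer complete genes exist. **SLLS** is sequential (imputed genes
  re-enter the pool); **ILLS** iterates from a row-average start. The
  **shrinkage** variants multiply the fitted coefficient vector by the
  positive-part James–Stein factor `clip(1 − (k−2)·σ̂²/‖w‖², 0, 1)` with
  `σ̂²` the residual variance of the local fit — damping overfitted local
  regressions; with k ≤ 2 the factor is 1.
- **Plugins** — any external executable taking an input TSV (missing =
  `NA`) and an output path. Output must keep shape and IDs, contain no
  missing values, and leave observed cells unchanged within 1e-9 (then
  snapped back bit-exactly). Violations, non-zero exits and timeouts
  (default 1 h) are reported with captured stderr.

Defaults follow the conventions of the algorithms' original descriptions
where they exist (k = 10 for the KNN family and LS; 10%-of-genes
neighbourhoods for LLS); every hyperparameter is exposed under the config
key `imputers.<id>`. An optional cross-validated choice of k for the LLS
family is deliberately not the default: auto-tuning inside the benchmark
would conflate algorithm quality with tuning budget.

## Synthetic data

`generate_complete` emulates small two-condition studies: `n_genes` genes
in `n_clusters` near-equal clusters, two equal sample groups, and a
fraction `de_fraction` of genes (spread round-robin across clusters, so
clustering truth and DE truth stay decoupled) shifted by
`effect_size · noise_sd` in group 2, plus iid Gaussian noise. Each cluster
sits at its own constant baseline level (6, 7, 8, … on a log2-like
intensity scale). Profiles are constant across samples by design:
replicate samples within a condition must share a gene's expected value,
because any deterministic sample-to-sample variation would both inflate
the within-group variance seen by the DE t-test and confound the
between-group comparison, destroying the planted DE ground truth. A
consequence worth knowing: cluster structure lives in baseline levels, the
zero-noise matrix has rank ≤ n_clusters (+1 with the DE shift), and
k-means recovers the planted partition exactly as noise → 0.

`generate_timecourse` instead gives each cluster a smooth profile
(alternating rise-then-fall tents and single-dip centred cosines at
growing amplitude), so neighbour-based imputers see genuine temporal
correlation and cluster-mean series have positive lag-1 autocorrelation.
Profiles are symmetric about the series midpoint, so the default
early-vs-late group split stays balanced for non-DE genes; even so, the
within-half profile variation depresses t-test power, and BLCI on time
courses should be interpreted qualitatively.

Defaults (300 × 6, 3 clusters, 10% DE at effect 2.5, noise SD 0.5, and the
study sizes used by the test suite and the acceptance script: two 300 × 6
datasets, B = 2) are chosen so a full 14-algorithm study completes in well
under a minute while every index keeps non-degenerate truth: ~24 of the 30
planted DE genes are recoverable at α = 0.05 with 3 vs 3 samples, cluster
separation is ~2 within-cluster SDs, and 5% masking leaves every gene
mostly observed.

What the generator does *not* emulate: intensity-dependent noise, spatial
artifacts, probe-level correlation, MNAR missingness (the framework's
missingness model is strictly MCAR), and realistic within-condition
biological variance. Passing benchmarks here therefore demonstrates
correctness of the machinery and sane relative behaviour of the
algorithms, not field performance on any particular real dataset; for
that, run the framework on your own complete matrices.

## Numerical choices and degenerate inputs

- Inverse-distance weights use `1/(d + 1e-12)`, so exact-duplicate
  neighbours dominate without dividing by zero.
- Iteration controls are `tol = 1e-4` (relative change of the missing
  cells) and `max_iter = 100` throughout; ILLS often uses its full budget,
  which is reported in diagnostics rather than treated as an error.
- Candidate correlations require ≥ 3 jointly observed samples and
  non-degenerate variance; otherwise the candidate is excluded, and a gene
  left with no candidates falls back to its row average (counted).
- Matrices are parsed as float64 throughout (no integer fast path);
  written values use `repr`, so write → read → write is byte-identical.
- Empty masks, all-missing genes, out-of-range percentages, duplicate
  IDs, ragged rows, unknown algorithm ids and unknown hyperparameter keys
  all fail fast with specific errors rather than propagating NaNs.

## Known limitations

- BPCA is a from-scratch variational implementation; on very small
  sample counts (≤ 4 columns) its advantage over row averages can vanish.
- CPP inherits k-means' sensitivity to k; the default k = 10 is a
  convention, and studies on synthetic data should pass the planted k.
- BLCI without real group labels (time courses) uses the half-split
  default and is the least interpretable of the three indices there.
- The plugin transport is file-based and spawns one process per
  imputation; very fast plugin algorithms pay a per-call overhead.
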