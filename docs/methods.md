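# Methods

## The clustering model

`chromclust` treats a quality-controlled scATAC-seq experiment as a binary
matrix `X ∈ {0,1}^{P×N}` of `P` peaks (called on the pseudo-bulk aggregate,
so intervals are merged and non-overlapping) by `N` cells. Binarization is
a modelling decision, not a convenience: a diploid locus yields at most two
deduplicated fragments per cell, so counts carry almost no information
beyond presence. Counts read from MatrixMarket files are clamped to 1 with
a logged warning.

### Peak weights

Two annotation-driven weights are multiplied per peak:

- **TSS proximity** (binary). A peak is proximal iff it overlaps the
  half-open window `[t − w/2, t + w/2)` around any TSS `t` on its
  chromosome, with the total window width `w` defaulting to 3 kb (i.e.
  TSS ± 1.5 kb; the window width is configurable). Proximal peaks are
  multiplied by `w_prox ∈ (0, 1]`; distal peaks keep weight 1. Fixing the
  distal weight at 1 and tuning only the ratio loses no generality: PCA
  directions are covariant under per-feature scaling, so only the ratio
  matters.
- **Reference DHS frequency** (continuous). `f_j ∈ [0,1]` is the fraction
  of reference cell/tissue types with a DNase-hypersensitive site in the
  peak's region, read from a 500 bp-binned bedGraph. A peak spanning
  several bins gets the overlap-length-weighted mean; genomic bins absent
  from the track count as frequency 0 (so an unannotated chromosome gives
  0). The weight is `(1 − f_j)^γ`, `γ ≥ 0` — any family that is monotone
  decreasing in `f` and collapses to 1 at `γ = 0` would do, since `γ` is
  tuned by the likelihood; this power family was chosen for smoothness and
  its exact unweighted limit. A peak with `f = 1` gets weight 0 and drops
  out of the PCA but remains visible to the multinomial likelihood, which
  always sees all peaks.

### Weighted PCA and k-means

Peak rows are scaled by their weights and mean-centered across cells; no
variance scaling is applied — the data are binary, and standardizing
features would undo the weights. Cell scores are the top right-singular
directions scaled by the singular values. For matrices up to 4×10⁶ entries
the exact dense SVD is used; above that, a truncated SVD on an implicitly
centered linear operator (fixed starting vector, so deterministic), which
matches the dense result to well under 1e-6 on test fixtures. Each
component's sign is fixed by requiring its peak-loading vector to sum
non-negative, making scores reproducible across runs and backends.

k-means (squared Euclidean, best of `n_init = 5` seeded restarts) clusters
the scores. Labels are canonicalized to 1..K by descending cluster size,
ties broken by the smallest original index, so results are comparable
across runs and the output is deterministic given the seed.

### Post-clustering multinomial likelihood

Cluster `k` with cell set `C_k` gets a peak distribution estimated from
pooled counts with additive smoothing,

```
p_jk = (Σ_{i∈C_k} x_ji + α) / (Σ_j Σ_{i∈C_k} x_ji + αP),
```

and a labelling is scored by `L = Σ_i Σ_j x_ji log p_{j,label(i)}`. The
multinomial coefficient is dropped: it depends only on the fixed matrix,
not on the labels, so it cancels in every comparison the likelihood is
used for. `α` defaults to 1 (Laplace); the same `α` is used for grid
scoring and final reporting so likelihoods are comparable across grid
points, and `α` is deliberately excluded from the grid for the same
reason. The likelihood evaluator refuses empty clusters — evaluation must
never silently change K.

### Hyperparameter search and cluster-number selection

`(w_prox, γ, n_pc)` are searched on a grid (defaults `{1.0, 0.5, 0.1} ×
{0, 1, 2, 3} × {5, 10, 15, 20}`; candidates are conventional placeholders
and fully configurable). The search is nested inside each candidate K, so
the elbow curve compares each K's best achievable likelihood. One SVD per
`(w_prox, γ)` pair at the largest `n_pc` serves all smaller `n_pc`
candidates, since the top-n components of one decomposition are the
n-component solution. Ties in likelihood resolve to smaller `n_pc`, then
larger `γ`, then larger `w_prox` (prefer the simpler projection, then the
stronger use of annotation).

K is chosen by an automated elbow rule: the K maximizing the perpendicular
distance from `(K, L_K)` to the chord joining the first and last curve
points, with the distance signed so only points on the concave side can
win; a collinear curve and ties resolve to the smallest K. With a single
candidate K the scan is skipped; with exactly two (too few for a chord
criterion) the larger likelihood wins.

### Reassignment

Winning labels are refined by alternating profile refits with per-cell
reassignment to `argmax_k Σ_j x_ji log p_jk` (ties to the smallest cluster
index), to a fixed point or `max_iter = 20`. A cluster emptied during
iteration is dropped and labels compacted, with a log message. Each sweep
is an argmax under fixed profiles followed by a refit, so the likelihood
trace is non-decreasing; this is asserted on every simulation run in the
test suite.

## Quality control

Cells with fewer than `min_peaks_per_cell` (default 500) accessible peaks
are removed first, then peaks accessible in fewer than
`min_cells_per_peak` (default 2) remaining cells. The order is fixed and
matters: cell filtering changes peak support. Both thresholds are
configuration, not science — real experiments need them tuned to the
platform.

## Synthetic data

`simulate_dataset` plants K clusters (default 3 × 50 cells) over `P`
peaks (default 2000) on a toy genome of fixed-width peaks spaced so that
each peak sits inside exactly one 500 bp DHS bin and a TSS window never
touches a neighbouring peak. A fraction (default 0.3) of peaks is
cluster-specific, split evenly among clusters: open at rate `q_high`
(default 0.2) in the owning cluster and `q_low` (default 0.02) elsewhere;
shared peaks are open at `q_high` everywhere. Per-cell depth factors are
log-normal (default μ=0, σ=0.5) and accessibility follows the saturating
capture model `P(x=1) = 1 − exp(−d·q)` — deeper sequencing asymptotically
reveals every truly open region; the alternative `min(1, d·q)` was
rejected for its kink. Cluster-specific peaks are placed distal with low
reference frequency (uniform on [0, 0.2]) and shared peaks high (uniform
on [0.6, 1.0]), with a configurable fraction (default 0.3) of shared peaks
made proximal — the regime in which annotation weighting should help, and
the default study condition for the end-to-end tests.

`downsample_bulk` emulates the purified-bulk benchmark: each pseudo-cell
draws a fixed number of reads multinomially from its type's normalized
bulk profile and binarizes. `make_block_bulk_profiles` synthesizes the
profiles (real purified bulk data lives in external accessions): all types
share one log-normal baseline landscape — most open chromatin is common
across related cell types — and each type's own block of peaks (default
`P/(2·n_types)`) gets an additive boost (default 0.5 over a baseline of
mean ≈ 1). The depth benchmark uses 4 types × 50 cells over 20 000 peaks
at 500 / 3 000 / 10 000 reads per cell. The peak count is deliberately
large relative to depth: with few peaks and many reads the binary matrix
saturates (every peak is hit at least once) and all signal vanishes, which
is a property of binarized downsampling, not of the clustering. At these
sizes mean purity rises from near chance at 500 reads to 1.0 at 10 000,
reproducing the qualitative depth dependence expected of scATAC-seq
clustering.

What the generator does *not* emulate: fragment-level artefacts (Tn5
sequence bias, PCR duplication), doublets, batch effects, peak-calling
errors, or correlated accessibility along the genome. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not performance on any real dataset.

## Evaluation

Overall purity is `(1/N) Σ_{predicted clusters} max_true count`; the
per-replicate statistic is overall purity, and "mean purity" across seeds
is its arithmetic mean. Purity is invariant to relabeling on either side
and bounded below by the largest true-class frequency. The adjusted Rand
index is included as a supplementary metric.

## Gene specificity and association

Peaks map to every gene with a TSS within half the window of any of the
peak's bases (same convention as proximity classification). For gene `g`
and cluster `k`, `a_gk` sums the cluster-k mean accessibility of the
gene's peaks — means, not sums, so cluster size does not bias the score —
and `s_gk = a_gk / Σ_k' a_gk'`, so rows sum to 1. Genes inaccessible in
every cluster are dropped with a warning.

The association test is rank-based and internal: Spearman correlation
between one cluster's specificity column and a per-gene statistic (larger
= more associated; transform GWAS p-values with −log10 first), with a
one-sided permutation null, `p = (1 + #{null ≥ observed}) / (1 + n_perm)`.
External gene-set tools can consume the exported covariate TSV instead.

## Determinism and seeds

All randomness flows through explicitly seeded NumPy generators; no global
state. The CLI fans a single `--seed` out to per-stage seeds via
`SeedSequence([seed, stage])`, so stages are independently rerunnable.
Repeated runs with the same inputs and seed are byte-identical apart from
log timestamps.

## Problem sizes

The test suite and the reproduction script run the default design (150
cells × 2000 peaks, full grid, K scanned 1..8) over ten seeds, and the
depth benchmark (200 cells × 20 000 peaks, three depths) over ten seeds
per depth — sizes chosen so a complete run finishes in about a minute on
one CPU while keeping every qualitative effect (elbow recovery, weighting
benefit, depth dependence, null calibration) measurable.

## Known limitations

- The multinomial model treats peaks as independent given the cluster;
  genomic autocorrelation is ignored.
- The elbow criterion needs at least three candidate K values and
  inherits the usual elbow-method sensitivity to the scanned range's
  endpoints.
- The reassignment step optimizes the smoothed likelihood greedily; it
  can merge clusters but never split them.
- The DHS weighting family `(1 − f)^γ` is one of many monotone choices;
  conclusions should not hinge on its exact form, and in practice the
  grid search can always fall back to `γ = 0`.
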