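"""Synthetic scATAC-seq data and the bulk-downsampling benchmark.

Two generators make every other module testable without downloads.

``simulate_dataset`` draws a binary peak-by-cell matrix with planted
cluster structure on a toy genome, together with matching TSS and
reference-DHS annotations. Cluster-specific peaks are distal and given
low reference DHS frequency; shared peaks are given high frequency and
a proximal/distal mix — the regime where annotation weighting should
help. Per-cell sequencing depth varies log-normally, and accessibility
follows a saturating capture model ``P(x=1) = 1 - exp(-d * q)``: more
depth asymptotically reveals every truly open region, mimicking how
read depth limits sensitivity in real assays.

``downsample_bulk`` builds synthetic single cells by multinomially
downsampling per-type bulk accessibility profiles to a fixed number of
reads per cell and binarizing, emulating benchmarks that degrade
purified bulk samples into pseudo-cells at controlled depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_formats import (
    DHS_BIN_WIDTH,
    ChromatinMatrix,
    DhsFrequencyTrack,
    PeakSet,
    TssAnnotation,
)

# toy-genome layout: fixed-width peaks on a regular grid so each peak
# sits inside exactly one 500 bp DHS bin and TSS windows never leak
# onto neighbouring peaks
_PEAK_SPACING = 4_000
_PEAK_OFFSET = 100
_PEAK_WIDTH = 300


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative description of a simulated dataset.

    Defaults give 3 clusters of 50 cells over 2000 peaks with
    accessibility rates 0.2 ("on") vs 0.02 ("off") per unit depth and
    log-normal depth variation (mu=0, sigma=0.5).
    """

    n_clusters: int = 3
    cells_per_cluster: int = 50
    n_peaks: int = 2000
    frac_cluster_specific: float = 0.3
    q_high: float = 0.2
    q_low: float = 0.02
    depth_lognormal: tuple[float, float] = (0.0, 0.5)
    proximal_fraction: float = 0.3
    dhs_freq_specific: tuple[float, float] = (0.0, 0.2)
    dhs_freq_shared: tuple[float, float] = (0.6, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.cells_per_cluster < 1 or self.n_peaks < 1:
            raise ValueError("counts must be positive")
        if not 0.0 < self.frac_cluster_specific < 1.0:
            raise ValueError("frac_cluster_specific must be in (0, 1)")
        if not 0.0 < self.q_high <= 1.0:
            raise ValueError("q_high must be in (0, 1]")
        if not 0.0 <= self.q_low <= self.q_high:
            raise ValueError("q_low must be in [0, q_high]")
        if not 0.0 <= self.proximal_fraction <= 1.0:
            raise ValueError("proximal_fraction must be in [0, 1]")
        for lo, hi in (self.dhs_freq_specific, self.dhs_freq_shared):
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError("DHS frequency ranges must satisfy 0 <= lo <= hi <= 1")


@dataclass(frozen=True)
class SyntheticDataset:
    """A simulated dataset with ground-truth cell labels."""

    matrix: ChromatinMatrix
    peaks: PeakSet
    tss: TssAnnotation
    dhs_track: DhsFrequencyTrack
    true_labels: np.ndarray
    rate_matrix: np.ndarray = field(repr=False, default=None)  # peaks x K


def expected_cell_depth(spec: SyntheticSpec, n_mc: int = 100_000, seed: int = 12345) -> np.ndarray:
    """Monte-Carlo expectation of per-cluster mean column sums.

    Integrates ``sum_j (1 - exp(-d q_j(k)))`` over the log-normal depth
    factor by brute-force sampling (independent of the generator's own
    randomness); used as an oracle in tests. Only two distinct rates
    occur per cluster, so the sum over peaks collapses to rate counts.
    """
    rng = np.random.default_rng(seed)
    mu, sigma = spec.depth_lognormal
    d = rng.lognormal(mu, sigma, size=n_mc)
    q = _rate_matrix(spec)
    out = np.empty(spec.n_clusters)
    for k in range(spec.n_clusters):
        rates, counts = np.unique(q[:, k], return_counts=True)
        per_draw = np.zeros(n_mc)
        for rate, count in zip(rates, counts):
            per_draw += count * (1.0 - np.exp(-d * rate))
        out[k] = per_draw.mean()
    return out


def _rate_matrix(spec: SyntheticSpec) -> np.ndarray:
    """Deterministic peaks x K matrix of per-unit-depth rates q_j(k)."""
    rng = np.random.default_rng(spec.seed)
    n_specific = int(round(spec.frac_cluster_specific * spec.n_peaks))
    specific_idx = rng.choice(spec.n_peaks, size=n_specific, replace=False)
    owner = np.full(spec.n_peaks, -1, dtype=np.int64)
    owner[specific_idx] = np.arange(n_specific) % spec.n_clusters
    q = np.full((spec.n_peaks, spec.n_clusters), spec.q_high)
    for k in range(spec.n_clusters):
        off = (owner >= 0) & (owner != k)
        q[off, k] = spec.q_low
    return q


def simulate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a complete synthetic dataset; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    n_peaks, k_clusters = spec.n_peaks, spec.n_clusters
    n_cells = k_clusters * spec.cells_per_cluster

    n_specific = int(round(spec.frac_cluster_specific * n_peaks))
    specific_idx = rng.choice(n_peaks, size=n_specific, replace=False)
    owner = np.full(n_peaks, -1, dtype=np.int64)
    owner[specific_idx] = np.arange(n_specific) % k_clusters
    is_specific = owner >= 0

    q = np.full((n_peaks, k_clusters), spec.q_high)
    for k in range(k_clusters):
        q[is_specific & (owner != k), k] = spec.q_low

    # toy genome geometry
    starts = np.arange(n_peaks, dtype=np.int64) * _PEAK_SPACING + _PEAK_OFFSET
    ends = starts + _PEAK_WIDTH
    peak_ids = np.array([f"peak{i:05d}" for i in range(n_peaks)], dtype=object)
    chroms = np.array(["chr1"] * n_peaks, dtype=object)
    peaks = PeakSet(chrom=chroms, start=starts, end=ends, peak_id=peak_ids)

    # proximal peaks: a random subset of the SHARED peaks; specific
    # peaks stay distal by construction
    shared_idx = np.flatnonzero(~is_specific)
    n_prox = int(round(spec.proximal_fraction * len(shared_idx)))
    prox_idx = np.sort(rng.choice(shared_idx, size=n_prox, replace=False))
    tss_pos = (starts[prox_idx] + ends[prox_idx]) // 2
    strands = np.where(np.arange(n_prox) % 2 == 0, "+", "-").astype(object)
    gene_ids = np.array([f"gene{i:05d}" for i in prox_idx], dtype=object)
    tss = TssAnnotation(
        chrom=np.array(["chr1"] * n_prox, dtype=object),
        tss_position=tss_pos,
        strand=strands,
        gene_id=gene_ids,
    )

    # reference DHS frequency: one 500 bp bin per peak (peaks sit inside
    # a single bin by construction)
    bin_starts = (starts // DHS_BIN_WIDTH) * DHS_BIN_WIDTH
    lo_s, hi_s = spec.dhs_freq_specific
    lo_h, hi_h = spec.dhs_freq_shared
    freq = np.where(
        is_specific,
        rng.uniform(lo_s, hi_s, size=n_peaks),
        rng.uniform(lo_h, hi_h, size=n_peaks),
    )
    dhs_track = DhsFrequencyTrack(
        chrom=chroms.copy(), bin_start=bin_starts, frequency=freq
    )

    # cells: log-normal depth factor, saturating accessibility model
    mu, sigma = spec.depth_lognormal
    depth = rng.lognormal(mu, sigma, size=n_cells)
    true_labels = np.repeat(np.arange(1, k_clusters + 1), spec.cells_per_cluster)
    prob = 1.0 - np.exp(-depth[None, :] * q[:, true_labels - 1])
    x = (rng.random((n_peaks, n_cells)) < prob).astype(np.int8)
    cell_ids = np.array([f"cell{i:04d}" for i in range(n_cells)], dtype=object)
    matrix = ChromatinMatrix(
        values=sp.csr_matrix(x), peak_ids=peak_ids, cell_ids=cell_ids
    )
    return SyntheticDataset(
        matrix=matrix,
        peaks=peaks,
        tss=tss,
        dhs_track=dhs_track,
        true_labels=true_labels,
        rate_matrix=q,
    )


def make_block_bulk_profiles(
    n_types: int,
    n_peaks: int = 20_000,
    seed: int = 0,
    specific_per_type: int | None = None,
    boost: float = 0.5,
    noise_sigma: float = 0.25,
) -> np.ndarray:
    """Block-structured stand-in for purified bulk accessibility profiles.

    All types share one log-normal baseline accessibility landscape —
    most open chromatin is common across related cell types — and each
    type's own block of peaks gets an additive intensity boost, the
    type-specific signal. Returns an n_types x n_peaks nonnegative
    count-intensity matrix. Synthetic: real purified bulk data lives in
    external accessions.
    """
    rng = np.random.default_rng(seed)
    if specific_per_type is None:
        specific_per_type = max(1, n_peaks // (2 * n_types))
    baseline = rng.lognormal(0.0, noise_sigma, size=n_peaks)
    profiles = np.tile(baseline, (n_types, 1))
    for t in range(n_types):
        lo = t * specific_per_type
        hi = min(lo + specific_per_type, n_peaks)
        profiles[t, lo:hi] += boost
    return profiles


def downsample_bulk(
    bulk_profiles: np.ndarray,
    cells_per_type: int = 50,
    reads_per_cell: int = 3000,
    seed: int = 0,
) -> tuple[ChromatinMatrix, np.ndarray]:
    """Synthesize single cells by downsampling bulk profiles.

    Each synthetic cell draws ``reads_per_cell`` reads multinomially
    from its type's normalized profile; per-peak counts are binarized
    (a locus yields at most a couple of deduplicated fragments, so
    presence is what survives).
    """
    profiles = np.asarray(bulk_profiles, dtype=np.float64)
    if profiles.ndim != 2:
        raise ValueError("bulk_profiles must be 2-D (types x peaks)")
    if np.any(profiles < 0):
        raise ValueError("bulk profiles must be nonnegative")
    sums = profiles.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("each bulk profile must have positive total mass")
    if reads_per_cell <= 0:
        raise ValueError("reads_per_cell must be positive")
    rng = np.random.default_rng(seed)
    n_types, n_peaks = profiles.shape
    p = profiles / sums[:, None]
    cols = []
    for t in range(n_types):
        counts = rng.multinomial(reads_per_cell, p[t], size=cells_per_type)
        cols.append((counts > 0).astype(np.int8).T)  # peaks x cells
    x = np.hstack(cols)
    labels = np.repeat(np.arange(1, n_types + 1), cells_per_type)
    peak_ids = np.array([f"peak{i:05d}" for i in range(n_peaks)], dtype=object)
    cell_ids = np.array(
        [f"cell_t{t}_{i:03d}" for t in range(n_types) for i in range(cells_per_type)],
        dtype=object,
    )
    matrix = ChromatinMatrix(
        values=sp.csr_matrix(x), peak_ids=peak_ids, cell_ids=cell_ids
    )
    return matrix, labels


def toy_annotations(
    n_peaks: int,
) -> tuple[PeakSet, TssAnnotation, DhsFrequencyTrack]:
    """Neutral annotations for matrices without a real genome.

    All peaks distal, no DHS coverage (frequency 0 everywhere), so all
    weights are 1 unless the weighting parameters say otherwise. Used
    by the downsampling benchmark, whose pseudo-cells have no genomic
    coordinates of their own.
    """
    starts = np.arange(n_peaks, dtype=np.int64) * _PEAK_SPACING + _PEAK_OFFSET
    peaks = PeakSet(
        chrom=np.array(["chr1"] * n_peaks, dtype=object),
        start=starts,
        end=starts + _PEAK_WIDTH,
        peak_id=np.array([f"peak{i:05d}" for i in range(n_peaks)], dtype=object),
    )
    tss = TssAnnotation(
        chrom=np.array([], dtype=object),
        tss_position=np.array([], dtype=np.int64),
        strand=np.array([], dtype=object),
        gene_id=np.array([], dtype=object),
    )
    track = DhsFrequencyTrack(
        chrom=np.array([], dtype=object),
        bin_start=np.array([], dtype=np.int64),
        frequency=np.array([], dtype=np.float64),
    )
    return peaks, tss, track
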