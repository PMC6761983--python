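"""Per-peak weights from TSS proximity and reference DHS frequency.

Two annotation-driven weights are multiplied per peak. A binary weight
downweights promoter-proximal peaks relative to distal regulatory
elements (enhancers carry sharper cell-type signal), and a continuous
weight ``(1 - f)**gamma`` downweights peaks whose genomic region is a
DNase hypersensitive site in a large fraction ``f`` of reference cell
types — ubiquitously open chromatin is uninformative for clustering.
The proximal multiplier and the exponent gamma are tuning parameters,
optimized downstream against the post-clustering multinomial
likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import DHS_BIN_WIDTH, DhsFrequencyTrack, PeakSet, TssAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightParams:
    """Tuning parameters of the peak weighting scheme.

    Parameters
    ----------
    w_proximal : float in (0, 1]
        Multiplier applied to TSS-proximal peaks; distal peaks get 1.
    gamma : float >= 0
        Exponent of the DHS-frequency weight ``(1 - f)**gamma``;
        0 disables frequency weighting.
    tss_window_bp : int
        Total width of the proximity window centred on each TSS
        (default 3000, i.e. TSS +/- 1500 bp).
    """

    w_proximal: float = 1.0
    gamma: float = 0.0
    tss_window_bp: int = 3000

    def __post_init__(self) -> None:
        if not 0.0 < self.w_proximal <= 1.0:
            raise ValueError(f"w_proximal must be in (0, 1], got {self.w_proximal}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.tss_window_bp <= 0:
            raise ValueError("tss_window_bp must be positive")


@dataclass(frozen=True)
class PeakWeights:
    """Per-peak annotation and the resulting final weight vector."""

    is_proximal: np.ndarray  # bool
    dhs_frequency: np.ndarray  # float in [0, 1]
    weight: np.ndarray  # float in [0, 1]

    def to_frame(self, peak_ids: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "is_proximal": self.is_proximal,
                "dhs_frequency": self.dhs_frequency,
                "weight": self.weight,
            }
        )
        if peak_ids is not None:
            df.insert(0, "peak_id", peak_ids)
        return df


def classify_tss_proximity(
    peaks: PeakSet, tss: TssAnnotation, window_bp: int = 3000
) -> np.ndarray:
    """Flag each peak as TSS-proximal (promoter-like) or distal.

    A peak is proximal iff it overlaps the half-open window
    ``[t - window_bp//2, t + window_bp//2)`` around any TSS ``t`` on the
    same chromosome. Peaks on chromosomes absent from the annotation are
    distal (logged, not an error).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    half = window_bp // 2
    flags = np.zeros(len(peaks), dtype=bool)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for c in np.unique(tss.chrom):
        tss_by_chrom[c] = np.sort(tss.tss_position[tss.chrom == c])
    missing: set[str] = set()
    for c in np.unique(peaks.chrom):
        mask = peaks.chrom == c
        positions = tss_by_chrom.get(c)
        if positions is None:
            missing.add(str(c))
            continue
        win_start = positions - half
        win_end = positions + half
        # windows share a width so sorting by start also sorts ends
        starts = np.asarray(peaks.start[mask])
        ends = np.asarray(peaks.end[mask])
        # peak [s, e) overlaps some window iff the first window whose end
        # exceeds s starts before e
        idx = np.searchsorted(win_end, starts, side="right")
        hit = (idx < len(win_start)) & (win_start[np.minimum(idx, len(win_start) - 1)] < ends)
        flags[mask] = hit
    if missing:
        logger.info(
            "chromosomes %s absent from TSS annotation; peaks there are distal",
            sorted(missing),
        )
    return flags


def annotate_dhs_frequency(
    peaks: PeakSet, track: DhsFrequencyTrack
) -> np.ndarray:
    """Reference DHS frequency per peak.

    Each peak gets the overlap-length-weighted mean frequency of the
    500 bp bins it intersects; genomic bins absent from the track count
    as frequency 0, so a peak on an unannotated chromosome gets 0.
    """
    freqs = np.zeros(len(peaks), dtype=np.float64)
    track_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(track.chrom):
        mask = track.chrom == c
        track_by_chrom[c] = (
            np.asarray(track.bin_start[mask], dtype=np.int64),
            np.asarray(track.frequency[mask], dtype=np.float64),
        )
    for i in range(len(peaks)):
        entry = track_by_chrom.get(peaks.chrom[i])
        if entry is None:
            continue
        bin_starts, bin_freqs = entry
        s, e = int(peaks.start[i]), int(peaks.end[i])
        lo = np.searchsorted(bin_starts, s - DHS_BIN_WIDTH + 1, side="left")
        hi = np.searchsorted(bin_starts, e, side="left")
        total = 0.0
        for j in range(lo, hi):
            b = bin_starts[j]
            overlap = min(e, b + DHS_BIN_WIDTH) - max(s, b)
            if overlap > 0:
                total += overlap * bin_freqs[j]
        freqs[i] = total / (e - s)
    return freqs


def compute_weights(
    proximal_flags: np.ndarray,
    frequencies: np.ndarray,
    params: WeightParams,
) -> PeakWeights:
    """Combine the two annotation weights into the final weight vector.

    ``weight_i = (w_proximal if proximal else 1) * (1 - f_i)**gamma``.
    With ``(w_proximal, gamma) = (1, 0)`` all weights are 1 and the
    downstream analysis reduces to unweighted PCA. A peak with reference
    frequency 1 gets weight 0: it drops out of the PCA but is retained
    by the multinomial likelihood, which sees all peaks.
    """
    proximal_flags = np.asarray(proximal_flags, dtype=bool)
    frequencies = np.asarray(frequencies, dtype=np.float64)
    if proximal_flags.shape != frequencies.shape:
        raise ValueError("proximal flags and frequencies must have equal length")
    if np.any(frequencies < 0) or np.any(frequencies > 1):
        raise ValueError("DHS frequencies must lie in [0, 1]")
    tss_weight = np.where(proximal_flags, params.w_proximal, 1.0)
    with np.errstate(invalid="ignore"):
        freq_weight = (1.0 - frequencies) ** params.gamma
    # 0**0 == 1 under numpy, which is the wanted gamma=0 identity limit
    weight = tss_weight * freq_weight
    return PeakWeights(
        is_proximal=proximal_flags,
        dhs_frequency=frequencies,
        weight=weight,
    )
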