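"""On-disk formats and validated in-memory containers.

All genomic coordinates are 0-based half-open (BED convention). The
accessibility matrix is stored as MatrixMarket coordinate format with a
BED3+name sidecar for peaks (rows) and a one-barcode-per-line text file
for cells (columns). The reference DHS frequency track is a 4-column
bedGraph with a fixed 500 bp bin width.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

if TYPE_CHECKING:  # pragma: no cover
    from .clustering import ClusterResult

logger = logging.getLogger(__name__)

DHS_BIN_WIDTH = 500


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakSet:
    """Sorted, non-overlapping genomic intervals defining matrix rows.

    Peaks are called on the pseudo-bulk aggregate upstream, so within a
    chromosome they are merged and never overlap.
    """

    chrom: np.ndarray  # str per peak
    start: np.ndarray  # int, 0-based
    end: np.ndarray  # int, half-open
    peak_id: np.ndarray  # unique str per peak

    def __post_init__(self) -> None:
        n = len(self.peak_id)
        if not (len(self.chrom) == len(self.start) == len(self.end) == n):
            raise ValueError("PeakSet fields must have equal length")
        if n and np.any(self.start >= self.end):
            bad = int(np.argmax(self.start >= self.end))
            raise ValueError(
                f"peak {self.peak_id[bad]!r} has start >= end "
                f"({self.start[bad]} >= {self.end[bad]})"
            )
        if len(np.unique(self.peak_id)) != n:
            raise ValueError("peak_id values must be unique")
        # sorted by (chrom, start) and non-overlapping within chromosome
        order = np.lexsort((self.start, self.chrom))
        if n and not np.array_equal(order, np.arange(n)):
            raise ValueError("peaks must be sorted by (chrom, start)")
        same_chrom = self.chrom[1:] == self.chrom[:-1]
        if n > 1 and np.any(same_chrom & (self.start[1:] < self.end[:-1])):
            bad = int(np.argmax(same_chrom & (self.start[1:] < self.end[:-1])))
            raise ValueError(
                f"peaks {self.peak_id[bad]!r} and {self.peak_id[bad + 1]!r} overlap"
            )

    def __len__(self) -> int:
        return len(self.peak_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "peak_id": self.peak_id,
            }
        )


@dataclass(frozen=True)
class ChromatinMatrix:
    """Sparse binary peak-by-cell accessibility matrix with row/column identity."""

    values: sp.csr_matrix  # peaks x cells, entries in {0, 1}
    peak_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.peak_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.peak_ids)} peak ids x {len(self.cell_ids)} cell ids"
            )
        if self.values.nnz and not np.all(np.isin(self.values.data, (0, 1))):
            raise ValueError("matrix entries must be binary (0/1)")

    @property
    def n_peaks(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TssAnnotation:
    """Transcription start sites; a gene may contribute several TSSs."""

    chrom: np.ndarray
    tss_position: np.ndarray  # int, 0-based
    strand: np.ndarray  # '+' or '-'
    gene_id: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_id)
        if not (len(self.chrom) == len(self.tss_position) == len(self.strand) == n):
            raise ValueError("TssAnnotation fields must have equal length")
        if n and np.any(self.tss_position < 0):
            raise ValueError("TSS positions must be non-negative")
        if n and not np.all(np.isin(self.strand, ("+", "-"))):
            raise ValueError("strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.gene_id)


@dataclass(frozen=True)
class DhsFrequencyTrack:
    """Reference DHS frequency per fixed 500 bp genomic bin.

    The frequency of a bin is the proportion of reference cell/tissue
    types showing a DNase hypersensitive site there, so values lie in
    [0, 1]. Bins absent from the track are treated as frequency 0.
    """

    chrom: np.ndarray
    bin_start: np.ndarray  # multiple of 500
    frequency: np.ndarray  # in [0, 1]

    def __post_init__(self) -> None:
        n = len(self.frequency)
        if not (len(self.chrom) == len(self.bin_start) == n):
            raise ValueError("DhsFrequencyTrack fields must have equal length")
        if n and np.any(self.bin_start % DHS_BIN_WIDTH != 0):
            raise ValueError(f"bin starts must be multiples of {DHS_BIN_WIDTH}")
        if n and (np.any(self.frequency < 0) or np.any(self.frequency > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        order = np.lexsort((self.bin_start, self.chrom))
        if n and not np.array_equal(order, np.arange(n)):
            raise ValueError("bins must be sorted by (chrom, start)")
        same = self.chrom[1:] == self.chrom[:-1]
        if n > 1 and np.any(same & (self.bin_start[1:] == self.bin_start[:-1])):
            raise ValueError("bins must be non-overlapping")

    def __len__(self) -> int:
        return len(self.frequency)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_peaks_bed(path: str | Path) -> PeakSet:
    """Read a BED3+name peak file (chrom, start, end, peak_id)."""
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    ids: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 4 tab-separated BED "
                    f"fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            ids.append(fields[3])
    return PeakSet(
        chrom=np.asarray(chroms, dtype=object),
        start=np.asarray(starts, dtype=np.int64),
        end=np.asarray(ends, dtype=np.int64),
        peak_id=np.asarray(ids, dtype=object),
    )


def read_barcodes(path: str | Path) -> np.ndarray:
    """Read a one-barcode-per-line cell identity file."""
    with open(path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if len(set(barcodes)) != len(barcodes):
        raise ValueError(f"{path}: duplicate barcodes")
    return np.asarray(barcodes, dtype=object)


def read_matrix(
    mtx_path: str | Path,
    peaks_bed_path: str | Path,
    barcodes_path: str | Path,
) -> tuple[ChromatinMatrix, PeakSet]:
    """Read the peak-by-cell matrix with its row and column identities.

    Counts greater than 1 in the MTX are clamped to 1 with a logged
    warning: at most two sequenceable fragments arise per locus per
    cell, so accessibility is modelled as an open/closed indicator.
    """
    peaks = read_peaks_bed(peaks_bed_path)
    barcodes = read_barcodes(barcodes_path)
    raw = scipy.io.mmread(str(mtx_path))
    mat = sp.csr_matrix(raw)
    if mat.shape != (len(peaks), len(barcodes)):
        raise ValueError(
            f"dimension mismatch: MTX declares {mat.shape[0]} x {mat.shape[1]} "
            f"but BED has {len(peaks)} peaks and barcode file has "
            f"{len(barcodes)} cells"
        )
    if mat.nnz == 0:
        logger.warning("matrix %s has no nonzero entries", mtx_path)
    n_clamped = int(np.sum(mat.data > 1))
    if n_clamped:
        logger.warning(
            "binarizing matrix: clamped %d entries > 1 to 1", n_clamped
        )
        mat.data = np.minimum(mat.data, 1)
    mat.data = mat.data.astype(np.int8)
    mat.eliminate_zeros()
    return (
        ChromatinMatrix(values=mat, peak_ids=peaks.peak_id, cell_ids=barcodes),
        peaks,
    )


def read_dhs_track(bedgraph_path: str | Path) -> DhsFrequencyTrack:
    """Read a 4-column bedGraph of reference DHS frequencies (500 bp bins)."""
    chroms: list[str] = []
    starts: list[int] = []
    freqs: list[float] = []
    with open(bedgraph_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(
                    f"{bedgraph_path}: line {lineno}: expected 4 bedGraph "
                    f"columns, got {len(fields)}"
                )
            start, end = int(fields[1]), int(fields[2])
            if end - start != DHS_BIN_WIDTH:
                raise ValueError(
                    f"{bedgraph_path}: line {lineno}: interval width "
                    f"{end - start} != {DHS_BIN_WIDTH}"
                )
            value = float(fields[3])
            if not 0.0 <= value <= 1.0:
                raise ValueError(
                    f"{bedgraph_path}: line {lineno}: frequency {value} "
                    f"outside [0, 1]"
                )
            chroms.append(fields[0])
            starts.append(start)
            freqs.append(value)
    return DhsFrequencyTrack(
        chrom=np.asarray(chroms, dtype=object),
        bin_start=np.asarray(starts, dtype=np.int64),
        frequency=np.asarray(freqs, dtype=np.float64),
    )


def read_tss(path: str | Path) -> TssAnnotation:
    """Read a TSS table: chrom, position, strand, gene_id (tab-separated)."""
    chroms: list[str] = []
    positions: list[int] = []
    strands: list[str] = []
    genes: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 columns "
                    f"(chrom, position, strand, gene_id)"
                )
            chroms.append(fields[0])
            positions.append(int(fields[1]))
            strands.append(fields[2])
            genes.append(fields[3])
    return TssAnnotation(
        chrom=np.asarray(chroms, dtype=object),
        tss_position=np.asarray(positions, dtype=np.int64),
        strand=np.asarray(strands, dtype=object),
        gene_id=np.asarray(genes, dtype=object),
    )


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def filter_matrix(
    m: ChromatinMatrix,
    min_peaks_per_cell: int = 500,
    min_cells_per_peak: int = 2,
) -> ChromatinMatrix:
    """Quality-control filter: drop shallow cells, then rare peaks.

    Cells with fewer than ``min_peaks_per_cell`` accessible peaks are
    removed first; peaks accessible in fewer than ``min_cells_per_peak``
    of the remaining cells are removed second. The order matters and is
    fixed: cell filtering changes peak support counts.
    """
    if min_peaks_per_cell < 0 or min_cells_per_peak < 0:
        raise ValueError("QC thresholds must be non-negative")
    col_sums = np.asarray(m.values.sum(axis=0)).ravel()
    keep_cells = col_sums >= min_peaks_per_cell
    if not keep_cells.any():
        raise ValueError(
            f"QC removed all {m.n_cells} cells (min_peaks_per_cell="
            f"{min_peaks_per_cell})"
        )
    vals = m.values[:, keep_cells]
    row_sums = np.asarray(vals.sum(axis=1)).ravel()
    keep_peaks = row_sums >= min_cells_per_peak
    if not keep_peaks.any():
        raise ValueError(
            f"QC removed all {m.n_peaks} peaks (min_cells_per_peak="
            f"{min_cells_per_peak})"
        )
    n_cells_dropped = int((~keep_cells).sum())
    n_peaks_dropped = int((~keep_peaks).sum())
    if n_cells_dropped or n_peaks_dropped:
        logger.info(
            "QC dropped %d cells and %d peaks", n_cells_dropped, n_peaks_dropped
        )
    return ChromatinMatrix(
        values=sp.csr_matrix(vals[keep_peaks]),
        peak_ids=m.peak_ids[keep_peaks],
        cell_ids=m.cell_ids[keep_cells],
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_peaks_bed(peaks: PeakSet, path: str | Path) -> None:
    peaks.to_frame().to_csv(path, sep="\t", header=False, index=False)


def write_barcodes(cell_ids: np.ndarray, path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\n" for c in cell_ids))


def write_mtx(m: ChromatinMatrix, path: str | Path) -> None:
    scipy.io.mmwrite(str(path), sp.coo_matrix(m.values), field="integer")


def write_tss(tss: TssAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": tss.chrom,
            "position": tss.tss_position,
            "strand": tss.strand,
            "gene_id": tss.gene_id,
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def write_dhs_track(track: DhsFrequencyTrack, path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": track.chrom,
            "start": track.bin_start,
            "end": track.bin_start + DHS_BIN_WIDTH,
            "frequency": track.frequency,
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def write_cluster_result(result: "ClusterResult", path: str | Path) -> None:
    """Write cell-to-cluster assignments as TSV plus a JSON sidecar.

    The sidecar (``<path>.params.json``) records the selected
    hyperparameters and the multinomial log-likelihood so a run can be
    reconstructed without rerunning the grid search.
    """
    if len(result.labels) == 0:
        raise ValueError("cannot write an empty cluster result")
    labels = np.asarray(result.labels)
    uniq = np.unique(labels)
    if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
        raise ValueError("cluster labels must be contiguous 1..K")
    pd.DataFrame({"cell_id": result.cell_ids, "cluster": labels}).to_csv(
        path, sep="\t", index=False
    )
    sidecar = Path(str(path) + ".params.json")
    sidecar.write_text(
        json.dumps(
            {"chosen": result.chosen, "loglik": result.loglik}, indent=2
        )
        + "\n"
    )


def read_cluster_result(path: str | Path) -> "ClusterResult":
    """Read back a cluster result written by :func:`write_cluster_result`."""
    from .clustering import ClusterResult

    df = pd.read_csv(path, sep="\t")
    sidecar = Path(str(path) + ".params.json")
    meta = json.loads(sidecar.read_text())
    return ClusterResult(
        labels=df["cluster"].to_numpy(dtype=np.int64),
        cell_ids=df["cell_id"].to_numpy(dtype=object).astype(str),
        chosen=meta["chosen"],
        loglik=float(meta["loglik"]),
        pc_scores=None,
    )
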