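"""Gene-level cell-type specificity and association testing.

Each gene's accessibility is attributed to clusters through the peaks
near its TSSs: the specificity of gene g for cluster k is the cluster-k
share of the gene's total cross-cluster mean accessibility, so rows sum
to 1. Cluster means (not sums) are used so cluster size does not bias
the score. A permutation test relates one cluster's specificity column
to an external per-gene association statistic (e.g. -log10 GWAS
p-values); covariate export produces input for external gene-set tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import spearmanr

from .io_formats import ChromatinMatrix, PeakSet, TssAnnotation
from .likelihood_model import _validate_labels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpecificityMatrix:
    """Genes x clusters specificity scores; rows sum to 1."""

    values: np.ndarray
    gene_ids: np.ndarray
    cluster_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.gene_ids), len(self.cluster_ids)):
            raise ValueError("shape does not match id lists")
        if len(self.gene_ids) and not np.allclose(
            self.values.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("specificity rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.cluster_ids
        ).rename_axis("gene_id")

    def column(self, cluster_id: str) -> np.ndarray:
        idx = int(np.flatnonzero(self.cluster_ids == cluster_id)[0])
        return self.values[:, idx]


def map_peaks_to_genes(
    peaks: PeakSet, tss: TssAnnotation, window_bp: int = 3000
) -> dict[str, list[str]]:
    """Map each peak to every gene with a TSS within window_bp/2 of it.

    Same half-open window convention as TSS-proximity classification: a
    peak maps to a gene iff it overlaps ``[t - window_bp//2,
    t + window_bp//2)`` for some TSS t of the gene. Peaks mapping to no
    gene are absent from the result.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    half = window_bp // 2
    mapping: dict[str, list[str]] = {}
    tss_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(tss.chrom):
        mask = tss.chrom == c
        order = np.argsort(tss.tss_position[mask], kind="stable")
        tss_by_chrom[c] = (
            np.asarray(tss.tss_position[mask][order], dtype=np.int64),
            np.asarray(tss.gene_id[mask][order], dtype=object),
        )
    for i in range(len(peaks)):
        entry = tss_by_chrom.get(peaks.chrom[i])
        if entry is None:
            continue
        positions, genes = entry
        s, e = int(peaks.start[i]), int(peaks.end[i])
        # overlap iff t - half < e and t + half > s
        lo = np.searchsorted(positions, s - half, side="right")
        hi = np.searchsorted(positions, e + half, side="left")
        hits = sorted(set(genes[lo:hi]))
        if hits:
            mapping[str(peaks.peak_id[i])] = [str(g) for g in hits]
    return mapping


def gene_specificity(
    m: ChromatinMatrix,
    labels: np.ndarray,
    peak_gene_map: dict[str, list[str]],
) -> SpecificityMatrix:
    """Cell-type specificity score per gene.

    ``a_gk`` sums, over the gene's peaks, the mean accessibility of the
    peak among cluster-k cells; ``s_gk = a_gk / sum_k' a_gk'``. Genes
    with zero accessibility in every cluster are dropped with a warning.
    """
    labels, k = _validate_labels(labels, m.n_cells)
    # cluster mean accessibility per peak: K x P
    counts = np.vstack(
        [
            np.asarray(m.values[:, labels == c].mean(axis=1)).ravel()
            for c in range(1, k + 1)
        ]
    )
    peak_index = {str(p): i for i, p in enumerate(m.peak_ids)}
    genes = sorted({g for gs in peak_gene_map.values() for g in gs})
    gene_index = {g: i for i, g in enumerate(genes)}
    a = np.zeros((len(genes), k))
    for peak_id, gene_list in peak_gene_map.items():
        p = peak_index.get(peak_id)
        if p is None:
            continue
        for g in gene_list:
            a[gene_index[g]] += counts[:, p]
    totals = a.sum(axis=1)
    keep = totals > 0
    if not np.all(keep):
        logger.warning(
            "dropping %d gene(s) with zero accessibility in every cluster",
            int((~keep).sum()),
        )
    s = a[keep] / totals[keep, None]
    return SpecificityMatrix(
        values=s,
        gene_ids=np.asarray(genes, dtype=object)[keep],
        cluster_ids=np.array([f"cluster_{c}" for c in range(1, k + 1)], dtype=object),
    )


def specificity_association(
    s_col: np.ndarray,
    gene_stats: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """One-sided permutation p-value for specificity/statistic association.

    The observed statistic is the Spearman correlation between one
    cluster's specificity column and a per-gene association statistic
    (larger = more associated; transform GWAS p-values to -log10
    first). The null is formed by permuting the gene statistics;
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    s_col = np.asarray(s_col, dtype=np.float64)
    gene_stats = np.asarray(gene_stats, dtype=np.float64)
    if s_col.shape != gene_stats.shape:
        raise ValueError("gene lists must be matched (equal length)")
    if s_col.size < 10:
        raise ValueError(f"need >= 10 shared genes, got {s_col.size}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = spearmanr(s_col, gene_stats).statistic
    rng = np.random.default_rng(seed)
    # Spearman is a Pearson correlation of ranks; permuting one rank
    # vector and correlating is cheap in closed form
    rs = pd.Series(s_col).rank().to_numpy()
    rt = pd.Series(gene_stats).rank().to_numpy()
    rs = (rs - rs.mean()) / rs.std()
    rt = (rt - rt.mean()) / rt.std()
    n = rs.size
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = float(rs @ rt[rng.permutation(n)]) / n
    return float((1 + np.sum(null >= observed)) / (1 + n_perm))


def export_gene_covariates(s: SpecificityMatrix, path: str | Path) -> None:
    """Write gene-by-cluster specificity as TSV (input for gene-set tools)."""
    s.to_frame().to_csv(path, sep="\t")


def read_gene_covariates(path: str | Path) -> SpecificityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return SpecificityMatrix(
        values=df.to_numpy(dtype=np.float64),
        gene_ids=df.index.to_numpy(dtype=object).astype(object),
        cluster_ids=df.columns.to_numpy(dtype=object),
    )
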