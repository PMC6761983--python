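"""Weighted PCA, k-means, and the likelihood-driven hyperparameter search.

The pipeline multiplies each peak row of the binary matrix by its
annotation weight, mean-centers peaks across cells, projects cells onto
the top principal components, and clusters the projections with
k-means. The weight parameters and number of components are chosen by
grid search to maximize the post-clustering multinomial likelihood; the
number of clusters is chosen by the elbow criterion over the per-k best
likelihoods, and the winning labels are refined by likelihood-based
reassignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, svds
from sklearn.cluster import KMeans

from .io_formats import ChromatinMatrix, DhsFrequencyTrack, PeakSet, TssAnnotation
from .likelihood_model import (
    ElbowCurve,
    multinomial_loglik,
    reassign_cells,
    select_n_clusters,
)
from .peak_weights import (
    PeakWeights,
    WeightParams,
    annotate_dhs_frequency,
    classify_tss_proximity,
    compute_weights,
)

logger = logging.getLogger(__name__)

# below this many matrix entries the exact dense SVD is used; larger
# problems go through an implicitly centered truncated SVD
_DENSE_SVD_MAX_ENTRIES = 4_000_000


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid for the likelihood-driven search.

    The candidate values are placeholders in the sense that any monotone
    weighting family works; they stay fully configurable. ``seed`` feeds
    the k-means initializations, ``n_init`` the number of restarts.
    """

    w_proximal_candidates: Sequence[float] = (1.0, 0.5, 0.1)
    gamma_candidates: Sequence[float] = (0.0, 1.0, 2.0, 3.0)
    n_pc_candidates: Sequence[int] = (5, 10, 15, 20)
    k_range: Sequence[int] = tuple(range(1, 9))
    seed: int = 0
    n_init: int = 5
    tss_window_bp: int = 3000

    def __post_init__(self) -> None:
        for name in ("w_proximal_candidates", "gamma_candidates", "n_pc_candidates", "k_range"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if any(n < 2 for n in self.n_pc_candidates):
            raise ValueError("n_pc candidates must be >= 2")
        if any(k < 1 for k in self.k_range):
            raise ValueError("k candidates must be >= 1")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


@dataclass
class ClusterResult:
    """Final clustering with the hyperparameters that produced it."""

    labels: np.ndarray  # 1..K per cell
    cell_ids: np.ndarray
    chosen: dict  # w_proximal, gamma, n_pc, k
    loglik: float
    pc_scores: np.ndarray | None
    grid_trace: pd.DataFrame | None = None
    elbow: ElbowCurve | None = None

    @property
    def n_clusters(self) -> int:
        return int(np.max(self.labels))


def weighted_pca(
    m: ChromatinMatrix, weights: PeakWeights, n_pc: int
) -> np.ndarray:
    """Project cells onto the top principal components of the weighted matrix.

    Peak rows are scaled by their weights and mean-centered across
    cells; no variance scaling is applied (the data are binary and
    rescaling would undo the weights). Zero-weight peaks drop out
    exactly. The sign of each component is fixed so its peak-loading
    vector has a non-negative sum, making the output deterministic.
    Returns a cells x n_pc score matrix.
    """
    w = np.asarray(weights.weight, dtype=np.float64)
    if w.shape[0] != m.n_peaks:
        raise ValueError("weight vector length does not match number of peaks")
    nz = w > 0
    n_active = int(nz.sum())
    if n_active == 0:
        raise ValueError("all peak weights are zero")
    if n_pc >= min(m.n_cells, n_active):
        raise ValueError(
            f"n_pc={n_pc} must be < min(n_cells={m.n_cells}, "
            f"active peaks={n_active})"
        )
    x = m.values[nz].astype(np.float64)
    x = sp.diags(w[nz]) @ x  # peaks x cells, row-scaled
    row_means = np.asarray(x.mean(axis=1)).ravel()

    if x.shape[0] * x.shape[1] <= _DENSE_SVD_MAX_ENTRIES:
        y = np.asarray(x.todense()) - row_means[:, None]
        u, s, vt = np.linalg.svd(y, full_matrices=False)
        u, s, vt = u[:, :n_pc], s[:n_pc], vt[:n_pc]
    else:
        xc = sp.csr_matrix(x)
        ones = np.ones(xc.shape[1])

        def matvec(v: np.ndarray) -> np.ndarray:
            v = np.asarray(v).ravel()
            return xc @ v - row_means * v.sum()

        def rmatvec(v: np.ndarray) -> np.ndarray:
            v = np.asarray(v).ravel()
            return xc.T @ v - ones * (row_means @ v)

        op = LinearOperator(xc.shape, matvec=matvec, rmatvec=rmatvec)
        v0 = np.random.default_rng(0).standard_normal(min(xc.shape))
        u, s, vt = svds(op, k=n_pc, v0=v0)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]

    # deterministic sign: each loading vector sums non-negative
    col_sums = u.sum(axis=0)
    flip = np.where(col_sums < 0, -1.0, 1.0)
    zero = np.isclose(col_sums, 0.0)
    if np.any(zero):
        first_nz = np.array(
            [u[np.argmax(np.abs(u[:, j]) > 0), j] for j in range(u.shape[1])]
        )
        flip = np.where(zero, np.sign(first_nz + (first_nz == 0)), flip)
    return (vt.T * s) * flip


def kmeans_cells(
    pc_scores: np.ndarray, k: int, seed: int = 0, n_init: int = 5
) -> np.ndarray:
    """Best-of-n_init k-means on the PC scores; labels 1..K.

    Labels are canonicalized by descending cluster size (ties broken by
    the smallest original k-means index) so runs are comparable.
    """
    n_cells = pc_scores.shape[0]
    if k > n_cells:
        raise ValueError(f"k={k} exceeds number of cells ({n_cells})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(pc_scores)
    sizes = np.bincount(raw, minlength=k)
    order = np.lexsort((np.arange(k), -sizes))  # size desc, index asc
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(1, k + 1)
    return remap[raw]


def _weight_grid_scores(
    m: ChromatinMatrix,
    proximal_flags: np.ndarray,
    frequencies: np.ndarray,
    grid: GridSpec,
) -> dict[tuple[float, float], np.ndarray]:
    """Cache of PC scores at max(n_pc) per (w_proximal, gamma) pair.

    The top-n components of one SVD equal the n-component solution, so
    smaller n_pc candidates are column slices of the cached scores.
    """
    max_npc = max(grid.n_pc_candidates)
    cache: dict[tuple[float, float], np.ndarray] = {}
    for w, g in product(grid.w_proximal_candidates, grid.gamma_candidates):
        params = WeightParams(w_proximal=w, gamma=g, tss_window_bp=grid.tss_window_bp)
        pw = compute_weights(proximal_flags, frequencies, params)
        cache[(w, g)] = weighted_pca(m, pw, max_npc)
    return cache


def _search_one_k(
    m: ChromatinMatrix,
    score_cache: dict[tuple[float, float], np.ndarray],
    grid: GridSpec,
    alpha: float,
    k: int,
) -> tuple[dict, np.ndarray, float, list[dict]]:
    """Best grid point at a fixed cluster number k."""
    rows: list[dict] = []
    best: tuple | None = None
    for (w, g), scores in score_cache.items():
        for n_pc in grid.n_pc_candidates:
            try:
                labels = kmeans_cells(scores[:, :n_pc], k, grid.seed, grid.n_init)
                ll = multinomial_loglik(m, labels, alpha).loglik
            except ValueError as exc:
                raise ValueError(
                    f"grid point (w_proximal={w}, gamma={g}, n_pc={n_pc}, "
                    f"k={k}) failed: {exc}"
                ) from exc
            rows.append(
                {"w_proximal": w, "gamma": g, "n_pc": n_pc, "k": k, "loglik": ll}
            )
            # maximize loglik; ties -> smaller n_pc, larger gamma, larger w
            key = (ll, -n_pc, g, w)
            if best is None or key > best[0]:
                best = (key, labels, ll, {"w_proximal": w, "gamma": g, "n_pc": n_pc, "k": k})
    assert best is not None
    _, labels, ll, chosen = best
    return chosen, labels, ll, rows


def grid_search(
    m: ChromatinMatrix,
    peaks: PeakSet,
    tss: TssAnnotation,
    dhs_track: DhsFrequencyTrack,
    grid: GridSpec,
    alpha: float = 1.0,
    k: int | None = None,
) -> ClusterResult:
    """Search (w_proximal, gamma, n_pc) at a fixed cluster number.

    Every grid point runs weights -> weighted PCA -> k-means, and is
    scored by the multinomial log-likelihood of the resulting labels;
    the same alpha is used for scoring and reporting so likelihoods are
    comparable across grid points. If ``k`` is omitted the grid's
    k_range must be a singleton.
    """
    if k is None:
        if len(grid.k_range) != 1:
            raise ValueError("grid_search needs a single k; pass k= or a singleton k_range")
        k = int(grid.k_range[0])
    flags = classify_tss_proximity(peaks, tss, grid.tss_window_bp)
    freqs = annotate_dhs_frequency(peaks, dhs_track)
    cache = _weight_grid_scores(m, flags, freqs, grid)
    chosen, labels, ll, rows = _search_one_k(m, cache, grid, alpha, k)
    scores = cache[(chosen["w_proximal"], chosen["gamma"])][:, : chosen["n_pc"]]
    return ClusterResult(
        labels=labels,
        cell_ids=m.cell_ids,
        chosen=chosen,
        loglik=ll,
        pc_scores=scores,
        grid_trace=pd.DataFrame(rows),
    )


def cluster(
    m: ChromatinMatrix,
    peaks: PeakSet,
    tss: TssAnnotation,
    dhs_track: DhsFrequencyTrack,
    grid: GridSpec = GridSpec(),
    alpha: float = 1.0,
    k_range: Sequence[int] | None = None,
) -> ClusterResult:
    """End-to-end clustering: grid search per k, elbow over k, reassignment.

    The hyperparameter search is nested inside each candidate k so the
    elbow curve compares each k's best achievable likelihood. With a
    single candidate k the elbow step is skipped; with two, the larger
    likelihood wins. The winning labels are refined by likelihood-based
    reassignment, and the reported log-likelihood is recomputed from
    the final labels.
    """
    ks = sorted(int(x) for x in (k_range if k_range is not None else grid.k_range))
    flags = classify_tss_proximity(peaks, tss, grid.tss_window_bp)
    freqs = annotate_dhs_frequency(peaks, dhs_track)
    cache = _weight_grid_scores(m, flags, freqs, grid)

    per_k: dict[int, tuple[dict, np.ndarray, float]] = {}
    all_rows: list[dict] = []
    for k in ks:
        chosen, labels, ll, rows = _search_one_k(m, cache, grid, alpha, k)
        per_k[k] = (chosen, labels, ll)
        all_rows.extend(rows)

    logliks = np.array([per_k[k][2] for k in ks])
    if len(ks) == 1:
        chosen_k = ks[0]
        elbow = None
    elif len(ks) == 2:
        chosen_k = ks[int(np.argmax(logliks))]
        elbow = None
    else:
        chosen_k = select_n_clusters(np.array(ks), logliks)
        elbow = ElbowCurve(
            k_values=np.array(ks), logliks=logliks, chosen_k=chosen_k
        )

    chosen, labels, _ = per_k[chosen_k]
    labels = reassign_cells(m, labels, alpha=alpha)
    final_ll = multinomial_loglik(m, labels, alpha).loglik
    scores = cache[(chosen["w_proximal"], chosen["gamma"])][:, : chosen["n_pc"]]
    return ClusterResult(
        labels=labels,
        cell_ids=m.cell_ids,
        chosen=chosen,
        loglik=final_ll,
        pc_scores=scores,
        grid_trace=pd.DataFrame(all_rows),
        elbow=elbow,
    )
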