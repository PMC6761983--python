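"""Post-clustering multinomial model.

Given a clustering, each cluster k is summarized by a probability
vector p_k over peaks, estimated from the pooled accessibility counts
of its cells with additive (Laplace-style) smoothing:

    p_jk = (sum_{i in C_k} x_ji + alpha) / (sum_j sum_{i in C_k} x_ji + alpha * P)

Each cell's accessible peaks are treated as draws from its cluster's
distribution, giving the log-likelihood

    loglik = sum_i sum_j x_ji * log p_{j, label(i)}

(the multinomial coefficient is constant across labelings of a fixed
matrix and is dropped). This likelihood scores hyperparameter grid
points, drives elbow-based selection of the cluster number, and powers
likelihood-based reassignment of individual cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import ChromatinMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MultinomialFit:
    """Cluster accessibility profiles and the resulting log-likelihood."""

    cluster_profiles: np.ndarray  # K x P, rows sum to 1
    alpha: float
    loglik: float

    def __post_init__(self) -> None:
        if not np.allclose(self.cluster_profiles.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("cluster profiles must each sum to 1")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")


@dataclass(frozen=True)
class ElbowCurve:
    """Log-likelihood as a function of the number of clusters."""

    k_values: np.ndarray
    logliks: np.ndarray
    chosen_k: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.k_values) <= 0):
            raise ValueError("k values must be strictly ascending")
        if self.chosen_k not in self.k_values:
            raise ValueError("chosen_k must be one of k_values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "loglik": self.logliks,
                "chosen": self.k_values == self.chosen_k,
            }
        )


def _validate_labels(labels: np.ndarray, n_cells: int) -> tuple[np.ndarray, int]:
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape != (n_cells,):
        raise ValueError(
            f"labels length {labels.size} does not match {n_cells} cells"
        )
    if labels.min(initial=1) < 1:
        raise ValueError("labels must be positive integers 1..K")
    k = int(labels.max())
    counts = np.bincount(labels, minlength=k + 1)[1:]
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0) + 1
        raise ValueError(f"empty cluster(s) {empty.tolist()}: relabel first")
    return labels, k


def _cluster_counts(m: ChromatinMatrix, labels: np.ndarray, k: int) -> np.ndarray:
    """K x P matrix of pooled accessibility counts per cluster."""
    indicator = sp.csr_matrix(
        (
            np.ones(m.n_cells),
            (labels - 1, np.arange(m.n_cells)),
        ),
        shape=(k, m.n_cells),
    )
    return np.asarray((indicator @ m.values.T).todense())


def multinomial_loglik(
    m: ChromatinMatrix, labels: np.ndarray, alpha: float = 1.0
) -> MultinomialFit:
    """Fit cluster profiles from labels and evaluate the log-likelihood.

    Raises on an empty cluster: likelihood evaluation must never
    silently change the number of clusters.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    labels, k = _validate_labels(labels, m.n_cells)
    counts = _cluster_counts(m, labels, k)
    profiles = (counts + alpha) / (
        counts.sum(axis=1, keepdims=True) + alpha * m.n_peaks
    )
    # x is binary, so the per-cluster pooled count against log p gives
    # the sum over member cells directly
    loglik = float(np.sum(counts * np.log(profiles)))
    return MultinomialFit(cluster_profiles=profiles, alpha=alpha, loglik=loglik)


def select_n_clusters(k_values: np.ndarray, logliks: np.ndarray) -> int:
    """Elbow selection: the k furthest above the chord through the endpoints.

    The distance is signed so that only points on the concave side of
    the chord (where a likelihood curve bends) can win; an exactly
    collinear curve has no elbow and resolves to the smallest k, as do
    ties.
    """
    k_values = np.asarray(k_values, dtype=np.float64)
    logliks = np.asarray(logliks, dtype=np.float64)
    if k_values.size != logliks.size:
        raise ValueError("k_values and logliks must have equal length")
    if k_values.size < 3:
        raise ValueError("elbow selection needs at least 3 points")
    if not np.all(np.isfinite(logliks)):
        raise ValueError("log-likelihoods must be finite")
    if np.any(np.diff(k_values) <= 0):
        raise ValueError("k values must be strictly ascending")
    x0, y0 = k_values[0], logliks[0]
    x1, y1 = k_values[-1], logliks[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = float(np.hypot(dx, dy))
    # signed perpendicular distance; positive above the chord
    dist = (dy * (k_values - x0) - dx * (logliks - y0)) / norm * -1.0
    best = int(np.argmax(np.round(dist, 12)))  # first max wins ties
    if dist[best] <= 1e-12:  # collinear or convex: no elbow
        return int(k_values[0])
    return int(k_values[best])


def reassign_cells(
    m: ChromatinMatrix,
    labels: np.ndarray,
    alpha: float = 1.0,
    max_iter: int = 20,
    return_trace: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[float]]:
    """Likelihood-based refinement of cluster memberships.

    Alternates fitting cluster profiles with reassigning every cell to
    the cluster maximizing ``sum_j x_ji log p_jk`` until the labels
    stop changing or ``max_iter`` is reached. A cluster emptied during
    iteration is dropped and the remaining labels compacted to 1..K'
    (logged). With ``return_trace`` the per-iteration log-likelihoods
    (after each refit) are returned as well.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    labels, _ = _validate_labels(labels, m.n_cells)
    trace: list[float] = []
    xt = sp.csr_matrix(m.values.T, dtype=np.float64)  # cells x peaks
    for _ in range(max_iter):
        fit = multinomial_loglik(m, labels, alpha)
        trace.append(fit.loglik)
        scores = xt @ np.log(fit.cluster_profiles).T  # cells x K
        new_labels = np.argmax(scores, axis=1) + 1  # ties: smallest cluster
        present = np.unique(new_labels)
        if len(present) < fit.cluster_profiles.shape[0]:
            logger.info(
                "reassignment emptied %d cluster(s); compacting labels",
                fit.cluster_profiles.shape[0] - len(present),
            )
            remap = np.zeros(int(present.max()) + 1, dtype=np.int64)
            remap[present] = np.arange(1, len(present) + 1)
            new_labels = remap[new_labels]
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    if return_trace:
        return labels, trace
    return labels
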