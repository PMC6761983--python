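"""Clustering quality metrics for benchmarks with known ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score


@dataclass(frozen=True)
class PurityReport:
    """Cluster purity against ground-truth labels.

    ``overall_purity`` is the fraction of cells whose predicted
    cluster's majority true label matches their own; rows of the
    contingency table are predicted clusters, columns true labels.
    """

    overall_purity: float
    per_cluster_purity: np.ndarray
    contingency: pd.DataFrame  # predicted x true counts


def cluster_purity(pred_labels, true_labels) -> PurityReport:
    """Purity of a predicted clustering against true labels.

    For each predicted cluster, count its most common true label; the
    sum over clusters divided by N is the overall purity. Invariant to
    relabeling of either side.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError(
            f"label vectors must match: {pred.shape} vs {true.shape}"
        )
    if pred.size == 0:
        raise ValueError("need at least one cell")
    contingency = pd.crosstab(pd.Series(pred, name="predicted"),
                              pd.Series(true, name="true"))
    maxes = contingency.to_numpy().max(axis=1)
    row_sums = contingency.to_numpy().sum(axis=1)
    return PurityReport(
        overall_purity=float(maxes.sum() / pred.size),
        per_cluster_purity=maxes / row_sums,
        contingency=contingency,
    )


def adjusted_rand(pred_labels, true_labels) -> float:
    """Adjusted Rand index: 1 for identical partitions, ~0 at chance."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(true, pred))
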