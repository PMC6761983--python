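import numpy as np
import pytest
import scipy.sparse as sp

from chromclust import (
    ChromatinMatrix,
    GridSpec,
    SyntheticSpec,
    cluster,
    simulate_dataset,
)


def make_matrix(arr, peak_prefix="p", cell_prefix="c") -> ChromatinMatrix:
    """Wrap a dense 0/1 array as a ChromatinMatrix with generated ids."""
    arr = np.asarray(arr, dtype=np.int8)
    n_peaks, n_cells = arr.shape
    return ChromatinMatrix(
        values=sp.csr_matrix(arr),
        peak_ids=np.array([f"{peak_prefix}{i}" for i in range(n_peaks)], dtype=object),
        cell_ids=np.array([f"{cell_prefix}{j}" for j in range(n_cells)], dtype=object),
    )


def random_binary_matrix(rng, n_peaks, n_cells, density=0.3) -> ChromatinMatrix:
    return make_matrix((rng.random((n_peaks, n_cells)) < density).astype(np.int8))


@pytest.fixture(scope="session")
def default_study():
    """Ten end-to-end runs on the default simulation design.

    K=3 clusters of 50 cells over 2000 peaks, accessibility rates
    0.2/0.02, log-normal depth (0, 0.5); full default grid with the
    cluster number scanned 1..8. Shared across the label-recovery,
    elbow-recovery and weighting-benefit checks.
    """
    runs = []
    for seed in range(10):
        ds = simulate_dataset(SyntheticSpec(seed=seed))
        res = cluster(
            ds.matrix, ds.peaks, ds.tss, ds.dhs_track, GridSpec(seed=seed)
        )
        runs.append((ds, res))
    return runs
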