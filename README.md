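# chromclust

Cell-type clustering of single-cell ATAC-seq (scATAC-seq) data.

scATAC-seq measures chromatin accessibility in individual cells, but the
resulting peak-by-cell matrix is extremely sparse, essentially binary (a
diploid locus yields at most two deduplicated fragments), and highly
variable even within a cell type. `chromclust` clusters cells from such a
matrix by exploiting two external sources of prior information about which
peaks are informative: distance to transcription start sites (distal
regulatory elements separate cell types better than promoters) and a
reference DNase-hypersensitivity (DHS) frequency track (regions open in
few reference cell types are more cell-type specific than ubiquitously
open chromatin).

## Method

Given a binary matrix `X` (peaks × cells), each peak `j` receives a weight

```
w_j = t_j · (1 − f_j)^γ ,   t_j = w_prox if peak j is TSS-proximal else 1,
```

where `f_j ∈ [0, 1]` is the reference DHS frequency of the peak's genomic
region (500 bp bins) and a peak is *proximal* iff it overlaps a 3 kb window
centred on any TSS. Rows of `X` are scaled by `w`, mean-centered, and cells
are projected onto the top `n_pc` principal components; k-means clusters the
projections.

The tuning parameters `(w_prox, γ, n_pc)` are chosen by grid search to
maximize a post-clustering multinomial likelihood: cluster `k` gets a peak
distribution `p_k` estimated from its pooled counts with additive-α
smoothing,

```
p_jk = (Σ_{i∈C_k} x_ji + α) / (Σ_j Σ_{i∈C_k} x_ji + αP),
L = Σ_i Σ_j x_ji log p_{j,label(i)} ,
```

the number of clusters `K` is selected by an automated elbow criterion on
the per-`K` best likelihoods (maximal perpendicular distance to the chord),
and cluster memberships are finally refined by iteratively reassigning each
cell to the cluster maximizing its likelihood.

The package also provides a synthetic-data generator and bulk-downsampling
benchmark, cluster-purity / adjusted-Rand evaluation, and gene-level
cell-type specificity scores with a permutation association test (e.g.
against gene-level GWAS statistics). See `docs/methods.md` for the full
model description and design choices.

## Worked example

```python
from chromclust import (GridSpec, SyntheticSpec, cluster, cluster_purity,
                        simulate_dataset)

ds = simulate_dataset(SyntheticSpec(seed=1))          # 3 clusters x 50 cells
res = cluster(ds.matrix, ds.peaks, ds.tss, ds.dhs_track, GridSpec(seed=1))
print("selected:", res.chosen)
print("log-likelihood: %.1f" % res.loglik)
print(res.elbow.to_frame().to_string(index=False))
print("purity vs truth: %.3f" % cluster_purity(res.labels, ds.true_labels).overall_purity)
```

prints

```
selected: {'w_proximal': 1.0, 'gamma': 3.0, 'n_pc': 5, 'k': 3}
log-likelihood: -336415.5
 k         loglik  chosen
 1 -340921.324056   False
 2 -338504.879379   False
 3 -336415.476078    True
 4 -335920.692460   False
 5 -335615.597938   False
 6 -334960.462369   False
 7 -334585.936664   False
 8 -334158.641687   False
purity vs truth: 1.000
```

The grid search picked a strong DHS-frequency weighting (γ = 3: the
cluster signal was planted in low-frequency distal peaks), the elbow found
the planted K = 3 where the likelihood curve bends, and all 150 cells were
assigned to their true cluster.

The same pipeline is available from the shell:

```
chromclust simulate --out-dir data --seed 1
chromclust cluster --mtx data/matrix.mtx --peaks data/peaks.bed \
    --barcodes data/barcodes.txt --tss data/tss.tsv --dhs data/dhs.bedgraph \
    --min-peaks-per-cell 1 --out-dir results --seed 1
chromclust enrich --mtx data/matrix.mtx --peaks data/peaks.bed \
    --barcodes data/barcodes.txt --tss data/tss.tsv \
    --clusters results/clusters.tsv --out-dir results
```

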