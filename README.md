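# smibench

Benchmarking missing-value imputation for **spatial metabolomics** (mass
spectrometry imaging, MSI).

MSI intensity matrices — one row per spatial spot, one column per annotated
metabolite — are extremely sparse: a large share of entries are zeros that
reflect technical non-detection (weak ionization, suppression, values below
the limit of quantification) rather than true biological absence. How those
values are imputed changes both numerical analyses and the spatial cluster
structure that downstream tissue-region analysis depends on. `smibench`
provides the full machinery to compare imputation strategies on such data:

* **Dropout simulators** with known ground truth: MCAR (uniform over all
  observed entries at rates 10–60%) and MNAR (left-censoring below a random
  per-metabolite quantile q ∈ [0.30, 0.60]).
* **Seven imputers**: mean, median, half-minimum, k-nearest-neighbour,
  iterative low-rank SVD with zero-clipping, missForest-style random
  forest, and a **spatial graph-convolutional autoencoder** — plus a
  file-based adapter for externally produced imputations.
* **Dual-dimension evaluation**: imputation accuracy at the hidden entries
  (NRMSE, RMSE, MAE, Pearson, cosine) and preservation of spatial cluster
  structure (silhouette, Calinski-Harabasz, NMI, ARI over a
  PCA → SNN-graph → modularity-clustering pipeline at resolutions 0.1–0.9).
* **Rank aggregation**: per-metric medians → min-max scaling (error
  metrics reversed) → average ranks per dimension.
* A **synthetic MSI generator** (spatially smooth, region-structured,
  zero-inflated lognormal intensities) so the whole benchmark runs without
  any external downloads.

## The graph autoencoder in brief

Spots form a k-nearest-neighbour graph over their (x, y) coordinates
(k = 8). Intensities are log1p-transformed and min-max scaled to [0, 1] per
metabolite; missing cells enter as 0 and are excluded from the loss by a
binary mask. Each layer propagates features over the normalized adjacency
with self-loops,

    H' = D̃^(-1/2) (A + I) D̃^(-1/2) · H · W + b,

through an encoder d → 32 → 16 → 16 (batch norm, ReLU, dropout 0.2 per
layer), a decoder through widths 64 and 128, and a final graph convolution
back to d with a sigmoid head. Training minimizes masked MSE with Adam
(lr 1e-3, weight decay 1e-5), early stopping (patience 20, max 1000
epochs). Because reconstruction at every spot borrows strength from its
spatial neighbourhood, the model exploits exactly the spatial smoothness
that real metabolite ion images exhibit — shuffling the graph's node labels
demonstrably destroys its advantage. The network is implemented on
numpy/scipy sparse matrices with hand-written backpropagation (gradients
are verified against finite differences in the test suite); full-batch
training of a 1,600-spot slice takes a few seconds on one CPU.

## Worked example

```python
import numpy as np
import smibench as sb

# generate an MSI-like dataset with ground truth
spec = sb.SyntheticSpec(seed=0)          # 40x40 grid, 60 metabolites, 4 regions
matrix, regions = sb.generate_dataset(spec)

# benchmark instance: zeros are non-detections; 30% MCAR dropout
data = sb.filter_for_accuracy(sb.drop_empty_spots(sb.zeros_to_missing(matrix)))
instance = sb.mask_mcar(data, rate=0.3, seed=1)
print(f"hidden {instance.n_masked} of {(~np.isnan(data.intensities)).sum()} observed entries")

# impute with the spatial graph autoencoder and with column means
gcn = sb.impute_gcn(instance, sb.GCNConfig(seed=1))
mean = sb.impute_mean(instance)
for res in (gcn, mean):
    r = sb.accuracy_metrics(res, instance)
    print(f"{res.method:>5}: NRMSE={r.nrmse:.3f}  Pearson={r.pearson:.3f}  MAE={r.mae:.2f}")
```

Output:

```
hidden 27358 of 91195 observed entries
  gcn: NRMSE=0.589  Pearson=0.832  MAE=6.88
 mean: NRMSE=0.952  Pearson=0.305  MAE=15.33
```

NRMSE is the root-mean-square error at the hidden entries divided by the
standard deviation of their true values, so 1.0 is the score of always
predicting the mean; the graph autoencoder recovers roughly 40% of that
residual spread by using spatial context, while mean imputation by
construction sits at ≈ 1 with near-zero correlation to the truth.

## Command line

```bash
smibench simulate --seed 3 --out sim                 # synthetic dataset + labels
smibench mask sim_matrix.csv --mechanism MNAR --rate 0.3 --seed 1 --out inst/
smibench impute inst/ --method gcn --param k_neighbors=8 --out imp/
smibench evaluate inst/ imp/imputed.csv --out metrics.json
smibench cluster imp/imputed.csv --algorithm slm --resolution 0.4 --out labels.csv
smibench benchmark --config run.yaml --out results/  # the whole grid
```

`run.yaml` holds a `BenchmarkConfig`: the dataset (synthetic spec or input
path), mechanisms, rates, per-method hyperparameter grids, clustering
algorithms and resolutions, and a seed. Re-running the same config
reproduces every report bit-exactly.

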