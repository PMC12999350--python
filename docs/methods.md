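# Methods

## Problem setting

Mass spectrometry imaging (MSI) produces a spot × metabolite intensity
matrix with 2-D coordinates per spot. A large fraction of entries are
zeros that predominantly reflect technical non-detection (weak ionization,
suppression, values below the limit of quantification) rather than true
biological absence, so the benchmark treats stored zeros as missing values
to impute (the reader exposes a `zeros_as_missing` toggle, default on).
`smibench` evaluates imputation methods along two dimensions: how
accurately they reconstruct artificially hidden values, and how well
downstream spatial clustering is preserved or improved.

## Dropout simulation

Two mechanisms create benchmark instances with known ground truth:

* **MCAR** hides exactly `round(rate · n_observed)` entries (rate grid
  0.1–0.6), drawn uniformly over *all* observed entries of the matrix.
  The draw is global, not stratified per metabolite; the choice is
  recorded in each instance's metadata. Counts use round-half-to-even.
* **MNAR** (left-censoring) selects `round(proportion · p)` metabolites
  uniformly, draws a truncation quantile q ~ Uniform[0.30, 0.60] per
  selected metabolite, and hides all observed values strictly below the
  empirical q-quantile (linear-interpolation convention). A column whose
  observed values are all equal censors nothing and is logged, not an
  error.

Masking applies only to entries that are observed in the reference;
observed entries off the mask are preserved bit-exactly in the instance,
which every test of the `MaskedDataset` invariants enforces.

Two filters precede the two tracks. The accuracy track keeps metabolites
with missing rate strictly below 10% so that the reference is
high-confidence; the clustering track only drops metabolites with more
than 80% missing (boundary cases: exactly 10% is dropped, exactly 80% is
kept — literal readings of "below 10%" and "more than 80%"). Spots with
no non-zero observed entry at all are removed first.

## Imputers

All imputers share one contract: complete, non-negative output with
observed cells preserved bit-exactly.

* **mean / median / half-minimum** — per-metabolite column statistics;
  half-minimum encodes the detection-limit assumption that non-detections
  sit below the smallest measured value.
* **kNN** (k = 10; sweep grid {5, 10, 15, 20, 30}) — spots are instances;
  Euclidean distance over mutually observed metabolites with the
  √(p/p_obs) rescaling; unweighted average of the k nearest spots
  observing the target metabolite, column mean as fallback. Implemented
  via scikit-learn's `KNNImputer`, which realizes exactly this rule.
* **iterative SVD** (rank = 10; sweep {5, 10, 15, 20, 30}) — missing cells
  start at the column mean (zero on the standardized scale); each
  iteration re-standardizes columns from the completed matrix, truncates
  the SVD at the given rank and overwrites missing cells, until the
  relative change of imputed cells drops below 1e-5 or 100 iterations.
  Re-estimating the standardization each iteration makes an exactly
  low-rank matrix a fixed point of the algorithm (a rank-1 matrix with one
  hidden cell is recovered to ~1e-10; with standardization frozen at
  observed-only statistics the fixed point is biased by the excluded
  cell's effect on the column mean, a ~2% error on small fixtures).
  Negative estimates are clipped to zero afterwards — intensities are
  physically non-negative — and the clipped count is reported.
* **random forest** (ntree = 100; sweep {100, 200, 300, 500, 800}) —
  missForest-style: initialize missing cells at column means, visit
  columns in increasing-missingness order, fit a regression forest
  (mtry = ⌈p/3⌉) on the rows observing the column, predict its missing
  rows; stop when the summed squared change between successive sweeps
  increases (returning the previous sweep) or after 10 sweeps.
* **GCN autoencoder** — see below.
* **external** — a file-based adapter that ingests matrices imputed by
  tools outside this package and validates the observed-preservation
  contract before scoring, so externally produced methods can enter the
  same ranking.

## The graph-convolutional autoencoder

Spots form a spatial k-nearest-neighbour graph (k = 8, union-symmetrized,
deterministic ties by (distance, index)). Features are log1p-transformed
and min-max scaled to [0, 1] per metabolite (per-metabolite scaling lets
the sigmoid output head reach each metabolite's full range); missing cells
enter the input as 0 — the scale floor, matching zero-as-non-detection
semantics — and are excluded from the loss through a binary observed
mask. A constant column is scaled to 0.5 and inverts exactly.

Each graph convolution is H′ = D̃^(−1/2)(A+I)D̃^(−1/2) · H · W + b. The
encoder maps d → 32 → 16 → 16 (three convolutions, each followed by batch
normalization, ReLU, and dropout 0.2); the decoder expands through widths
64 and 128 (same block structure) and a final graph convolution back to d
with a sigmoid head, so reconstructions live in (0, 1). The stated decoder
widths are not a strict mirror of the encoder; a `mirror_decoder` switch
provides the mirrored variant (16 → 32) without claiming either is
canonical. Training is full-batch: MSE over observed cells only, Adam
(lr 1e-3, weight decay 1e-5, coupled L2), at most 1000 epochs with early
stopping at patience 20; the best-loss parameter snapshot (including
batch-norm running statistics) is restored. Batch normalization uses batch
statistics during optimization and running averages at imputation time.
Imputation runs the trained network in inference mode, inverts the min-max
and log1p transforms (which guarantees non-negativity), and replaces
missing cells only.

The network is implemented directly on numpy/scipy sparse matrices with
hand-written backpropagation through every layer; gradients are verified
against central finite differences in the test suite. Full-batch training
on a 1,600-spot slice takes seconds per hundred epochs on one CPU.

Hyperparameter sweep axes mirror the sensitivity analysis: k ∈ {4, 6, 8,
10, 12}, hidden dims ∈ {(16), (32,16), (24,16,8), (32,24,16,8),
(64,32,16,8)}, embedding ∈ {4, 8, 16, 32, 64}. Defaults are the selected
configuration k = 8, hidden (32, 16), embedding 16 (the final clustering
setting, chosen over the ablation baseline of 8).

## Evaluation

**Accuracy** is computed at masked entries only (observed entries are
preserved by contract, so whole-matrix metrics would dilute error toward
zero): RMSE, NRMSE = RMSE / population SD of the true masked values, MAE,
Pearson correlation and cosine similarity of the paired vectors. Degenerate
cases (zero truth variance, zero norm, constant vector) are reported as
undefined rather than NaN-propagated. For methods with sweep grids, the
configuration minimizing NRMSE per (dataset, mechanism, rate) is selected
and all five metrics are reported under it; ties break to the
lexicographically smallest setting.

**Clustering** uses the standard graph pipeline: log1p, per-metabolite
z-scaling, PCA (full SVD solver, ≤30 components — also the feature space
for silhouette and Calinski-Harabasz), shared-nearest-neighbour graph
(k = 20, Jaccard weights including self), and modularity community
detection at resolutions 0.1–0.9. Three optimizers are exposed: igraph's
multilevel Louvain, Leiden (RB-configuration modularity), and a
single-level Leiden run with the plain modularity objective as an
SLM-equivalent; exact parity with Seurat's implementations is not claimed.
`cluster_fixed_k` bisects the resolution to hit an exact cluster count,
merging smallest-into-nearest-centroid (or k-means splitting) when no
resolution lands exactly. NMI uses arithmetic normalization; ARI is
chance-corrected. The non-imputed "raw" baseline fills missing cells with
zero.

**Ranking**: per metric, the median across datasets (mechanisms and rates
pooled) represents method-level performance; medians are min-max scaled to
[0, 1] per metric; NRMSE/RMSE/MAE are reversed (1 − scaled) so higher is
better; methods are ranked per metric with average ranks on ties; the
dimension rank is the mean of per-metric ranks over the accuracy set
(NRMSE, RMSE, MAE, Pearson, cosine) or the clustering set (silhouette,
Calinski-Harabasz, ARI, NMI). Averaging normalized scores instead of ranks
is available behind `use_scores=True`.

## Synthetic data

The generator emulates the statistical structure the benchmark relies on:
a rectangular raster of spots; per-metabolite lognormal base intensity
(log-mean uniform in [1, 3], i.i.d. log-noise SD 0.4); contiguous regions
(equal-width stripes or Voronoi cells of random seeds) with half the
metabolites enriched in one random region by a multiplicative fold-change;
spatially correlated noise made by Gaussian-blurring white noise at a
3-spot length scale (normalized to unit SD so smoothing does not shrink
amplitude); and independent Bernoulli zeroing of cells. The default
fixture is a 40 × 40 grid, 60 metabolites, 4 regions, 5% zero-inflation —
small enough for fast tests, large enough for clustering to be meaningful.
Clustering-recovery checks use a fold-change of 4 and 30% zero-inflation:
a strong but realistic regional signature under intermediate missingness.

What the generator does *not* emulate: instrument physics (ionization
suppression, matrix effects), m/z-domain structure, intensity-dependent
background sparsity (its zero-inflation is MCAR-like by design, keeping
mechanisms separable — MNAR structure is introduced only by the masking
module), or the very large spot counts of real slices. Passing tests
therefore demonstrate correctness of the machinery and the *relative*
behaviour of methods under controlled spatial smoothness and regional
structure, not performance on any particular real tissue.

## Numerical and design choices

* Coordinates are continuous reals; Euclidean distance throughout; no
  raster assumption anywhere but the generator.
* Masked-count rounding is half-to-even; the empirical quantile is the
  linear-interpolation convention; "below" is strictly less than.
* SVD tolerance 1e-5 (relative change of imputed cells), cap 100
  iterations; non-convergence returns the current estimate with a warning
  flag in the diagnostics rather than an error.
* Graph normalization adds self-loops before the symmetric degree
  normalization; the stored edge set itself has none. Note the normalized
  operator's row sums can exceed 1 on irregular graphs (they equal 1
  exactly only on regular graphs); its spectral radius is at most 1.
* Reproducibility: every stochastic step (generator, masking, forest
  seeds, network initialization and dropout, community detection) is
  driven by explicit integer seeds; re-running a benchmark config
  reproduces every report file bit-exactly.
* Problem sizes in the test suite and acceptance script: the 40 × 40 / 60-
  metabolite fixture for graph-autoencoder comparisons, a 20 × 20 / 30-
  metabolite raster for the random-forest runs (forest cost scales with
  spots × trees × columns), and 3–5 mask seeds for head-to-head medians —
  sizes at which every compared effect is already unambiguous.

## Known limitations

* MAI (mechanism-aware imputation) is not reimplemented; externally
  produced matrices can be scored through the `external` adapter.
* No imzML/METASPACE ingestion; inputs are delimited text exports.
* Whether real METASPACE exports encode non-detection as 0 or as absent
  cells cannot be resolved from the data description; the reader's toggle
  covers both conventions.
* The clustering pipeline approximates, but does not bit-match, Seurat's
  SNN pruning and SLM implementation.
* Runtime/peak-memory scalability is out of scope (hardware-dependent).
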