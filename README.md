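# cytovoxel

Batch alignment and interpretable featurization for multi-batch flow and mass
cytometry. The package is aimed at immunologists and computational biologists
who need to pool cytometry samples acquired in different runs, by different
instruments or at different sites, and then ask quantitative questions —
which cell populations separate patient groups, how well does a classifier
generalize across acquisition batches — without losing the interpretability
of classical marker-based gating.

## What it does

1. **Pre-processing** — reads FCS files (a minimal FCS 2.0/3.0/3.1 reader and
   writer is included) or delimited event tables, applies spillover
   compensation, sequential polygonal scatter gating, a logicle
   (biexponential, Parks–Moore; defaults T = 262 144, W = 0.5, M = 4.5,
   A = 0) or arcsinh (cofactor 5, scaled by 1/8) intensity transform, and
   fixed-count subsampling.

2. **Autoencoder batch alignment** — a small symmetric autoencoder
   (encoder 64–32–16, mirrored decoder, ReLU, batch-norm) is trained on cells
   pooled from all batches with a dual objective

   `L = MSE(f(x), x) + β(t) · W_hist(f(X), ref)`

   where the first term anchors every cell to itself (preserving per-cell
   structure) and the second is the mean over markers of the 1-D
   histogram-Wasserstein distance between each batch's output marginals and
   the pooled histograms of a randomly chosen reference batch. β decays
   linearly during training. The result is a pure cell-wise map applied
   uniformly to every sample.

3. **Hypervoxel featurization** — each marker's normalized range is cut at
   0.3 and 0.6 into LOW (−), MED (+) and HIGH (++); every two- or
   three-marker combination contributes the fractions of cells in its
   3^k voxels, giving features with names like `CD8++/CD27-/CCR7-`. Features
   whose maximum occupancy across samples is below 1% are dropped.

4. **Benchmarking** — per-channel Wasserstein distances, Euclidean distances
   between voxel feature vectors, symmetrized KL-divergence matrices over
   50-bin per-channel histograms, the technical/biological (diagonal/
   off-diagonal) KL ratio, and Spearman correlation of distance matrices.
   A low KL ratio means batches were corrected *without* collapsing real
   biological differences.

5. **Classification and screening** — gradient-boosted trees (500 trees,
   depth 6) on z-scored voxel features with inverse-frequency class weights,
   F1-tuned decision thresholds, held-out-batch or leave-one-batch-out
   evaluation (ROC/PR curves and areas, confusion matrices), and univariate
   feature screening by two-sided Mann-Whitney U or one-way ANOVA with
   Benjamini–Hochberg adjustment.

A seeded synthetic-data module generates multi-batch cytometry-like datasets
with known ground truth (Gaussian-mixture cell populations, monotone
per-channel batch distortions, a planted biological outlier and a planted
class-associated voxel effect), so the whole pipeline is testable without
external data.

## Worked example

```python
from cytovoxel import synthetic
from cytovoxel.align import TrainConfig, train_alignment, apply_alignment
from cytovoxel.metrics import per_channel_wasserstein
from cytovoxel.voxels import build_feature_matrix, filter_sparse

# two batches of the same subjects; batch2 carries a +0.2 intensity offset
spec = synthetic.shifted_pair_spec(offset=0.2, n_cells_per_sample=3000, seed=0)
data = synthetic.generate_dataset(spec)

model = train_alignment(list(data), reference_batch="batch1",
                        cfg=TrainConfig(epochs=150, seed=0))
aligned = [apply_alignment(model, s) for s in data]

pre = per_channel_wasserstein(data["WT1@batch1"], data["WT1@batch2"])[1]
post = per_channel_wasserstein(aligned[0], aligned[1])[1]
print(f"replicate Wasserstein before alignment: {pre:.3f}")
print(f"replicate Wasserstein after alignment:  {post:.3f}")

features = filter_sparse(build_feature_matrix(aligned))
print(f"voxel features retained: {features.data.shape[1]}")
```

Output:

```
replicate Wasserstein before alignment: 0.197
replicate Wasserstein after alignment:  0.015
voxel features retained: 131
```

The two numbers are the mean, over the six markers, of the 1-D Wasserstein
distance between technical replicates of the same subject: the planted batch
shift (0.2 in normalized units) dominates before alignment and is reduced by
roughly an order of magnitude after it. The retained columns are the
interpretable voxel occupancies (e.g. `CD3-/CD19++/CD8-` ≈ 0.38 — the B-cell
compartment) that feed benchmarking and classification.

The same flow is available from the shell:

```bash
cytovoxel simulate --preset benchmark --out data/
cytovoxel run --config pipeline.yaml --out runs/demo
```

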