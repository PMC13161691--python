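# Methods

## The alignment model

Each cytometry sample is a set of cells measured on a shared marker panel,
with intensities brought to normalized display units in [0, 1] by a logicle
or arcsinh transform. Batch effects appear as per-channel shifts and
deformations of the marker distributions between acquisition runs. The
aligner is an autoencoder `f : R^m -> R^m` (encoder widths 64, 32, 16,
mirrored decoder, ReLU activations, batch normalization after every hidden
layer) trained on cells pooled from every batch and applied identically to
every cell, the reference batch's cells included, so there is no
reference/non-reference discontinuity.

The training objective per minibatch is

    L = mean[(f(x) - x)^2]  +  beta(t) * s * H(f(X), ref)

* The reconstruction term anchors each output cell to its own input —
  the model assumption is that the technical correction is small relative to
  the biological structure, so staying close to the input is the right prior.
* `H` is the distribution-matching term: for each acquisition batch present
  in the minibatch, the mean over markers of the 1-D Wasserstein distance
  between the batch's output histogram and the reference batch's pooled
  histogram (50 bins over [0, 1]), averaged over batches. Matching each
  batch separately matters: matching only the pooled minibatch histogram
  lets two batches settle on opposite sides of the target — in experiments
  on a planted 0.2 offset, pooled matching capped the correction near
  50–65% while per-batch matching reaches ~94%.
* During training the histogram is made differentiable by soft binning
  (each cell's unit mass interpolated linearly between the two nearest bin
  centers). On inputs lying exactly at bin centers the soft histogram equals
  the hard-binned one, which is how the surrogate is validated against the
  evaluation-time `histogram_loss`.

### Loss balance and the scale `s`

A distributional distance has O(1/n) per-cell gradients of roughly constant
magnitude (a "transport force"), while the reconstruction term is a spring
whose pull grows with the displacement being corrected. In per-coordinate
mean conventions, a histogram weight of `beta = 0.002` alone can hold a
displacement of only ~`beta/2` in normalized units — three orders of
magnitude less than a realistic batch shift. The published weight therefore
only makes sense jointly with an implementation-specific loss scaling, which
is not derivable from the weight itself. We make that scaling explicit:
`hist_grad_scale` (default 2000) multiplies the histogram term inside the
training objective so the two gradient magnitudes are commensurate
(`beta0 * s = 4` vs. a reconstruction gradient of `2 * shift = 0.4` at a
0.2 displacement, a 10x driving margin). The default was fixed by a
planted-shift probe: 600 corrects ~65–75% of a 0.2 offset, 2000 corrects
~94% with negligible drift of the reference batch (< 0.006), 6000 is noisier
and worse. Evaluation metrics never include this scale.

### The beta schedule

`beta(t)` decays linearly from `beta0 = 0.002` to a floor of
`beta_floor_frac * beta0` (default 0.25). The floor is load-bearing: the
reconstruction term pulls permanently back toward the identity map, so if
beta reached zero the final epochs would be pure reconstruction and would
undo the learned correction. Decaying to a quarter keeps the correction in
place while letting late epochs refine individual cell placement.

### What alignment does and does not preserve

The learned map is multivariate: a cell's corrected value in one channel
depends on all its markers. Population proportions travel through the map
unchanged (cells in the same region move together), which is why occupancy
features of a biologically divergent outlier stay distinct after alignment.
Per-channel rank order, however, is only approximately preserved: cells
whose intensities differ by more than the within-population scale (~0.15)
keep their order in ≥ 95% of pairs, but near-ties straddling population
boundaries can swap. Exact coordinate-wise monotonicity is not enforced by
the architecture and should not be assumed downstream.

## Hypervoxel features

Marker intensities are discretized at fixed thresholds 0.3 and 0.6 (MED is
the closed interval [0.3, 0.6]; exact threshold values are MED). All marker
combinations of size k = 3 by default (k ∈ {2, 3} on request) are
enumerated in panel order; each combination contributes 3^k occupancy
fractions in a canonical order (levels vary fastest on the last marker),
named `CD8++/CD27-/CD16-` style. Per combination the fractions sum to 1
before filtering; occupancies are invariant to cell order and to duplicating
every cell. Features whose maximum occupancy across samples is strictly
below 1% are removed ("below 1%" is strict: a maximum of exactly 0.01
survives). Values outside [0, 1] are clipped before discretization,
consistent with the aligner's output contract.

## Benchmarking metrics

* **Per-channel Wasserstein.** By default the exact empirical distance
  (integral of the absolute CDF difference); a binned variant (cumulative
  sum difference × bin width over shared edges) matches the training loss
  convention. Under the binned form the distance between point masses in the
  first and last of B bins is (B−1)/B of the range, not the full range —
  the exact form is used wherever that distinction matters.
* **Symmetrized KL.** Per-channel 50-bin histograms over [0, 1] with a
  pseudocount of 1e-6 per bin added before renormalization (disjoint
  supports stay finite); 0.5·[KL(P‖Q) + KL(Q‖P)] summed over channels
  (a flag switches to averaging). Direction-resolved KL is not reported by
  default because heat-map-style replicate comparisons are symmetric.
* **Preservation ratio.** Mean divergence over technical-replicate pairs
  divided by mean divergence over biologically distinct pairs. Successful
  correction without collapse drives the numerator down while the
  denominator stays up; the planted outlier's mean divergence to other
  subjects must stay above the technical-replicate level.
* **Voxel Euclidean distance** between feature vectors, and **Spearman
  correlation** of distance-matrix upper triangles as a global-topology
  check.

## Classification and screening

XGBoost with 500 trees of depth 6, single-threaded and seeded for
reproducibility; features z-scored with the population-sd convention,
statistics fitted on training rows only (zero-variance features map to 0
with a warning); inverse-frequency class weights. Binary decision thresholds
maximize F1 over the sorted unique validation scores with ties broken toward
the lower threshold. Evaluation is always across technical conditions: a
held-out batch or leave-one-batch-out folds that partition samples exactly
once; ROC area equals the normalized Mann-Whitney U statistic and is checked
against brute-force pair counting. Multi-class tasks report one-vs-rest ROC
areas and argmax labels; threshold tuning is binary-only.

Feature screening uses the two-sided Mann-Whitney U test for two groups
(exact enumeration when the combined n ≤ 20 without ties, otherwise the
normal approximation with tie and continuity correction) and one-way ANOVA
for three or more. Tables report raw p (the ranking key), Benjamini–Hochberg
adjusted p, and each feature's occupancy range.

## The synthetic-data generator

Samples are Gaussian-mixture draws in normalized marker space: five
splenocyte-like populations (CD4 T, CD8 T, B, NK, myeloid) on a six-marker
panel, with subject-level biological variability as a log-normal jitter of
mixture proportions (sd 0.10–0.12) and a small jitter of population means.
Batch effects are monotone per-channel distortions
`clip(gain · x^exponent + offset + noise, 0, 1)`, spanning shift, scale and
nonlinear deformations of the kind produced by varying antibody dilutions
between replicate stain cocktails. Ground truth is planted explicitly: a
lymphocyte-deficient outlier subject (divergent proportions), and a class
effect that moves one population's mixture weight so a chosen voxel's
expected occupancy differs between classes by a stated shift (0.15 by
default). Every sample's random stream derives from
(master seed, biological id, batch id) via a stable hash, so adding samples
never perturbs existing ones and identical specs are bit-reproducible.

The generator does **not** emulate spectral spillover, doublets,
acquisition-time drift within a run, heavy-tailed or zero-inflated intensity
distributions, or inter-marker correlation structure beyond the mixture
itself. Passing tests on these data therefore demonstrate that the
algorithms recover planted effects under controlled conditions, not that
real instruments' artifacts are handled; real data additionally require the
compensation/gating/transform path.

## Numerical choices

* Logicle: Parks–Moore parameterization; the forward transform inverts the
  biexponential by vectorized bisection (64 halvings, interval < 1e-18),
  normalized so T maps to display 1; values below the domain minimum clamp
  to display 0 (compensated data can be slightly negative), values above
  clamp at display 1.5.
* Binned Wasserstein uses cumulative-sum difference × bin width over shared
  edges; histograms normalized to sum 1.
* Gating counts boundary points as inside (deterministic; shapely `covers`).
* Batch-norm statistics are frozen at inference so a cell's output never
  depends on the composition of the batch it arrives in.
* Reference-batch choice is a uniform seeded draw over sorted batch ids.
* Minibatches smaller than 32 cells per batch group skip the histogram term
  (too noisy); minibatches of fewer than 2 cells are skipped entirely
  (batch-norm needs a variance).

## Problem sizes

The test and acceptance workloads run the method at reduced scale chosen to
exercise every code path on a single CPU: planted-shift correction with
2 subjects × 2 batches × 6 000 cells and 300 training epochs; preservation
with 4 subjects (one outlier) × 3 batches × 4 000 cells; classification with
40 subjects per class, 4 batches, 2 000 cells per sample. Production-scale
settings (30 000 cells per sample, 1 200 epochs) are the library defaults.

## Known limitations

* Alignment assumes a shared marker panel; multi-panel integration is out of
  scope, as are GAN- or optimal-transport-based alternatives.
* The aligner cannot distinguish a batch effect from a biological effect
  that is perfectly confounded with batch; the planted-outlier check only
  shows robustness when the outlier is a minority of its batch.
* Thresholds 0.3/0.6 are fixed, not adaptive; populations sitting on a
  threshold split across voxels.
* Spillover estimation from single-color controls and automated gate
  learning are not provided; gates and spillover matrices are inputs.
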