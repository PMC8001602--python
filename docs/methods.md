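# Methods

## Problem and model

The positive class — newly grown leaves (NGL) — occupies roughly 3–4% of
the pixels of a very-high-resolution RGB canopy scene and appears as
bright, light-green, clustered patches over tree crowns. Two properties
drive the design: the background canopy is smooth and spatially coherent
(well approximated by a low-rank matrix per channel), and the targets are
rare, localised deviations from it (sparse). The pipeline therefore
(1) amplifies sparse structure before learning, and (2) segments with
encoder–decoder networks whose pooling depth is deliberately small so that
few-pixel targets survive the spatial bottleneck.

## Sparse enhancement

Each channel `P` (h×w matrix) is decomposed as `P ≈ L + S` and replaced by
`E = clip(P + S)` in the declared value range. Pixels where `S = 0` are
unchanged; anomalous pixels are pushed further from the local background,
raising target-background contrast. The decomposition runs per channel
independently, which keeps `E = P + S` literally true channel-wise; the
same configuration is applied to training and test scenes.

Two kernels:

* **GoDec** (non-convex, budgeted). Alternates `L ← rank-r SVD truncation
  of (P − S)` and `S ← k-largest-|·| entries of (P − L)`. Both half-steps
  minimise the Frobenius residual over one variable, so the residual
  sequence is non-increasing; iteration stops when its relative change
  falls below `tol` (default 1e-6) or after `max_iter` (default 100).
  `S` is initialised by hard-thresholding `P` itself: starting from
  `S = 0` lets an isolated strong spike dominate the first rank-r fit and
  the iteration can stall with the spike inside `L`. The truncated SVD is
  exact (LAPACK, or ARPACK `svds` with a fixed deterministic start vector
  for thin slices of large matrices), not randomised — channel matrices
  here are at most ~1300×1000, where exactness is affordable.
  Defaults `r = 2` and `k = ⌈0.04·h·w⌉` encode the smooth-background /
  3–4%-prevalence assumptions.

* **Principal component pursuit** (convex). Minimises
  `‖L‖* + λ‖S‖₁` subject to `P = L + S` via the standard inexact
  augmented-Lagrangian scheme (singular-value soft-thresholding for `L`,
  entry-wise shrinkage for `S`, multiplier update, `μ ← 1.5μ`), with
  `λ = 1/√max(m, n)` by default and `μ₀ = 1.25/‖P‖₂`. The constraint is
  driven to a relative Frobenius residual ≤ `tol`; failure to converge
  within `max_iter` is reported as a flag, not an exception. This solver
  is an algorithmic stand-in for the stable-PCP family: it solves the same
  convex program, but no claim is made about matching any specific
  quasi-Newton variant.

Degenerate inputs: an all-zero matrix returns `L = S = 0` with relative
residual defined as 0 (avoiding 0/0).

## Architectures

All six networks share one vocabulary: 3×3 same-padding convolutions with
ReLU, each followed by batch normalization; 2×2 max pooling; parameter-free
2× nearest-neighbor upsampling; channel-concatenation skip links (U-Net
convention, applied right after the matching upsampling); and a 1×1
convolution + sigmoid head producing one probability per pixel. Inputs are
scaled to [0, 1] and must have spatial dims divisible by 2^pooling_depth.

* `segnet`: canonical 13-convolution encoder (widths 64,64 / 128,128 /
  256,256,256 / 512,512,512 / 512,512,512) mirrored by a 13-convolution
  decoder — 26 convolutions, 5 pools, 5 upsamplings, no skips.
* `unet`: 4 pooling levels, two convolutions per level (64…512), a
  1024-wide bottleneck pair, and a concat skip at every level.
* `3l_sn` / `3l_usn`: three levels, two convolutions per level, widths
  64/128/256, mirrored decoder; `3l_usn` adds a concat skip per level.
* `2l_usn` / `2l_conv_usn`: two levels, widths 64/128, skips at both;
  `2l_conv_usn` inserts one extra conv+BN pair (width 256) at the
  bottleneck encoder stage.

The exact per-level convolution counts and widths of the shallow variants
are a declared convention (two conv+BN per level, the named widths
64/128/256, mirrored decoders): the variants are defined by pooling depth,
skip placement and the one extra bottleneck block, and those properties are
what the tests pin down.

`width_scale` multiplies every filter width (floor 4) without changing the
layer sequence, pooling depth or skip topology. It exists so that
desk-scale experiments train in minutes on one CPU; architecture censuses
and capacity comparisons always use scale 1.

## Losses

For ground truth `p ∈ {0,1}` and prediction `p̂ = σ(z)`:

* CE: `mean −[p log p̂ + (1−p) log(1−p̂)]`
* WCE (β ∈ (1,2)): the positive term is multiplied by β.
* BCE (β ∈ (0,1)): `mean −[β p log p̂ + (1−β)(1−p) log(1−p̂)]`; at the
  default β = 0.99 the positive/negative weight ratio is 99.

Natural logarithms; `p̂` is clamped to `[1e-7, 1−1e-7]`. The two β's share
a letter in the literature but are distinct parameters with incompatible
ranges; they are validated separately. The closed-form logit gradient
`w₊ p (p̂−1) + w₋ (1−p) p̂` feeds backpropagation directly.

Note on optimizer interaction: with Adam (the training default), a uniform
rescaling of the loss does not change the update direction or size, so on a
patch containing a single class the three losses behave identically; β
matters exactly when both classes are present, where it sets the relative
pull of target versus background pixels.

## Training

Mini-batch Adam (lr 1e-3, batch 8, ≤100 epochs, early-stop patience 10) on
sliding-window patches, with 10% of patches held out for validation when
there are at least five (the parameters achieving the best monitored loss
are restored). These hyperparameters are package defaults chosen as
ordinary practice for small segmentation networks; they are all exposed in
`TrainConfig`/`SegmentationModel`. One integer seed fans out
deterministically to initialisation, the validation split, and batch
shuffling; identical config + seed reproduces identical results on one
device. Non-finite loss aborts with a diagnostic. The networks run on an
in-package numpy engine (im2col convolutions, exact backprop); no external
deep-learning framework is used.

## Tiling

0-based, row-major, half-open windows. Patch count
`(⌊(W−w)/sx⌋+1)·(⌊(H−h)/sy⌋+1)`; border remainders are dropped. On the
1300-wide × 1000-tall study geometry with 260×200 windows this gives 289
training patches at strides (65, 50) and 25 test patches at strides
(260, 200). Window sizes are quoted width × height; that orientation is
the only one consistent with both counts on that scene. Prediction
stitching requires non-overlapping specs; pixels not covered by any window
are flagged and excluded from metrics (overlap averaging is out of scope).

## Evaluation

Error matrix with rows = detection, columns = truth (`Pa` TP, `Pb` FP,
`Pc` FN, `Pd` TN). Accuracy `(Pa+Pd)/N`; Cohen's kappa
`(Po − Pe)/(1 − Pe)` (NaN when both marginals are degenerate and
identical, where it is undefined); ROC by threshold sweep with trapezoidal
AUC (ties count ½, hard 0/1 maps degenerate to three-point curves); hard
decisions use threshold 0.5 on the sigmoid score. Tri-color maps: hits
red, false alarms blue, misses yellow, true negatives the source grayscale.

## Synthetic scenes

`generate_scene` builds: per channel, a base canopy color plus up to
`background_rank − 1` separable smooth fields (outer products of
Gaussian-smoothed profiles) — so the noise-free background has numerical
rank ≤ `background_rank` — plus i.i.d. Gaussian texture noise (sd 0.02);
then `n_target_clusters` disc-blob clusters grown to hit the requested
prevalence within ±20% relative, whose pixels get an additive color shift.
Defaults: 512×512, rank 3, 12 clusters, prevalence 0.035, shift
(+0.08, +0.20, +0.03) — bright light green against the (0.16, 0.34, 0.12)
base. A `low_contrast()` preset shrinks the shift to
(+0.03, +0.08, +0.012) for hard scenes, and an optional distractor paints
bright non-green texture in the lower-right corner without labels, to
probe false-alarm behavior. `generate_paired_areas` yields two
independent scenes for the cross-area protocol (train on one, test on the
other, symmetric).

What passing on these scenes shows: the decomposition, enhancement,
tiling, training, stitching and evaluation machinery is correct, and
enhancement helps when targets are sparse additive anomalies on a low-rank
background. What it does not show: performance on real canopy imagery,
where target texture, mixed pixels, registration error and non-separable
backgrounds all matter.

## Desk-scale experiment sizes

End-to-end runs in the test suite use `width_scale = 0.125` (widths
8/16/32 for the shallow nets), 20–30 epoch budgets, at most 64 training
patches (subsampled with the run seed when the tiling yields more), and
256×256 scenes for the 5-seed enhancement-vs-none ablation (512×512 for
the single headline run). These sizes are the package's declared
desk-scale configuration: they keep a full run in the minutes range on one
CPU while leaving every stage of the method intact.

## Known limitations

* GoDec is a non-convex heuristic: support recovery is only guaranteed in
  the planted regimes the property tests exercise (spikes well above the
  background scale, adequate budgets).
* The PCP solver uses full SVDs per iteration; fine up to ~1300×1000
  channels, not intended for much larger rasters.
* Overlapping-window prediction averaging is not implemented (test tiling
  is non-overlapping by design).
* TIFF I/O round-trips pixel data but does not interpret geo-referencing
  tags.
* Grassmann-average and online-probabilistic robust-PCA kernels are not
  implemented; the kernel interface (`rpca.decompose`) is the extension
  point.
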