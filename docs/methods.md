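# Methods

## Problem and approach

Damaged or diseased grapevine berries (rot, sunburn, atrophy, malformation)
must be found before harvest, but labelled examples of damage are scarce and
heterogeneous while images of healthy berries are abundant. `vitisvae`
therefore treats the task as one-class anomaly detection: a variational
autoencoder (VAE) is trained exclusively on image patches of healthy
berries, and at inference time the reconstruction error of a patch — low
for anything resembling the healthy training distribution, high for
deviations — serves as its anomaly score. Per-pixel error maps, reassembled
over the patch grid, localize the damage inside an image.

## Pipeline

1. **Region of interest.** A binary berry mask restricts processing to
   image regions containing berry bunches. Masks are consumed as inputs;
   for synthetic scenes a colour-threshold segmenter
   (`patches.color_threshold_segmenter`: green-dominant pixels, small
   components removed) stands in for a learned segmentation model. It is a
   deliberately simple heuristic, adequate only for the rendered scenes
   (IoU against the generator's ground-truth mask > 0.9 in practice).
2. **Patching.** The image is tiled with non-overlapping 130 x 130 windows
   on a grid anchored at the top-left corner (residual margins discarded;
   0-based, half-open windows). A window is kept when at least
   `coverage_threshold` (default 0.1) of its pixels lie in the ROI. Kept
   tiles are downsampled to 64 x 64 by exact local-mean (area) averaging,
   which is anti-aliased and mean-preserving. A patch is labelled anomalous
   when its source window contains at least `min_anomalous_pixels`
   (default 30, ~0.18 % of the window) of ground-truth damage — enough to
   be robust against single-pixel mask noise.
3. **Model.** See below.
4. **Scoring and thresholding.** A patch's score is the spatial mean of the
   pixel-wise loss map (l1, MSE or BCE) between the patch and its
   deterministic reconstruction. A single decision threshold is chosen to
   maximize accuracy by exhaustive search over all midpoints between
   consecutive sorted unique scores plus one cut below the minimum and one
   above the maximum — exact, deterministic, O(n log n); accuracy ties
   resolve to the smaller threshold. The rule is `score > threshold =>
   anomalous`. Per-stage accuracies reuse the globally optimized threshold.
5. **Heatmaps.** Per-patch MSE maps (MSE penalizes strong deviations
   hardest) are upscaled back to 130 x 130 by nearest neighbour (constant
   regions survive exactly) and placed at their origins; the grid is
   non-overlapping so no blending occurs. Overlays render the map through
   a blue-to-red colormap (per-image min-max normalization by default; a
   fixed absolute scale is available for cross-image comparability). An
   optional post-filter removes above-threshold connected components
   smaller than `min_area` pixels (off by default) — specular highlights
   and mask-border slivers produce exactly such few-pixel false positives.

## Architectures

**FPL-VAE.** Encoder: four 4 x 4 convolutions with stride 2 (no pooling),
each followed by batch normalization and LeakyReLU (slope 0.2), taking
64 x 64 x 3 to 4 x 4 x 256; channel widths (32, 64, 128, 256). Two fully
connected heads map the flattened 4096-vector to the latent mean and
log-variance (latent dimension 100). Decoder: a fully connected expansion
back to 4 x 4 x 256, then four stages of nearest-neighbour 2x upsampling
followed by a 3 x 3 stride-1 convolution with replication padding
(batch norm + LeakyReLU between stages, widths 256 -> 128 -> 64 -> 32 -> 3)
and a final sigmoid so outputs lie in [0, 1]. Latent dimension and channel
widths follow the Hou-style feature-perceptual VAE this design descends
from. Sampling uses the reparameterization z = mu + exp(log sigma^2 / 2) * eps
with eps ~ N(0, 1); scoring and all evaluation passes fix eps = 0, making
inference deterministic.

**Baseline AE (SSIM-AE / FPL-AE).** Four 3 x 3, stride-1, padding-1
convolutional encoder layers and four decoder layers with batch norm and
LeakyReLU. A stride-1/padding-1 stack performs no spatial downsampling, so
compression is purely by channel narrowing through a middle bottleneck
convolution (default 8 channels, widths (16, 16, 16, 16) elsewhere). The
two variants share the architecture and differ only in training loss.

All networks are implemented in the package's own numpy layer library
(`vitisvae.nn`, NHWC layout): convolution as k x k shifted-slice BLAS
matmuls, batch normalization with running statistics, Adam, and manual
backward passes for every layer (each verified against central finite
differences in the test suite).

## Losses

**Feature perceptual loss (FPL).** Input and reconstruction are passed
through a *frozen* feature extractor delta; at tap layer l with feature maps
of shape (C_l, H_l, W_l),

    L_rec^l = 1/(2 C_l W_l H_l) * sum_{c,w,h} (delta(x)^l - delta(x_hat)^l)^2,
    L_rec   = sum_l L_rec^l .

Only the encoder/decoder are updated; the extractor never is. Two extractor
modes exist:

- `pretrained_vgg19`: the 19-layer VGG topology, weights loaded from a
  user-supplied local `.npz` (fingerprint-checked); taps default to
  relu1_1, relu2_1, relu3_1. No weights ship with the package; without a
  weights file this mode raises a configuration error.
- `deterministic_random` (default for tests and the synthetic study): a
  seeded, He-initialized 3-layer CNN (16/32/64 channels, strides 1/2/2,
  LeakyReLU, taps after every activation). Random frozen CNN features are a
  standard self-contained surrogate for pretrained perceptual features and
  make every result in this repository bit-reproducible offline.

Pixel inputs in [0, 1] are normalized inside the extractor adapter only
(VGG: ImageNet channel statistics; random mode: shift/scale to [-1, 1]);
raw pixel losses always use the un-normalized values.

**KL divergence.** Closed form for the diagonal Gaussian posterior against
the standard normal prior: `1/2 sum_i (mu_i^2 + sigma_i^2 - 1 - log sigma_i^2)`,
non-negative, zero exactly at the prior.

**Total objective.** `L = alpha * L_KL + lambda * L_rec`. The weights are
not prescribed by the method's sources. **Defaults: alpha = 1e-5,
lambda = 1.** Rationale: the FPL above is normalized per feature element,
whereas the ancestral design this VAE follows weights an *unnormalized*
feature loss roughly 1:2 against the KL term; with feature maps of ~2.6e5
elements that corresponds to a reconstruction:KL ratio of order 1e5 after
normalization. With alpha = lambda = 1 the KL term dominates by a factor
of ~20 and the posterior collapses to a blurry class mean with no anomaly
separation; alpha = 1e-5 restores the intended balance. Both weights are
exposed in the run config and logged with every run.

**Pixel losses.** Elementwise l1, squared error, or binary cross-entropy
(inputs clamped to [1e-7, 1 - 1e-7]), channel-averaged to one map per
patch; the patch score is the spatial mean.

**SSIM.** The public `ssim` metric delegates to scikit-image (Gaussian
window, sigma 1.5, window 11). Training the SSIM-AE additionally needs a
gradient, so `SSIMLoss` re-implements Gaussian-windowed SSIM with a
hand-derived backward pass (chain rule through the window convolutions;
zero-padded borders with the similarity map cropped by the window radius,
so the boundary handling never enters the loss and the blur operator is
self-adjoint). Its value agrees with scikit-image to ~1e-10 and its
gradient with finite differences; both facts are asserted in the tests.

## Training protocol

One-class: the trainer *refuses* any patch labelled anomalous — this is the
method's central premise, enforced as a hard error. Batch size 64
(validation 16), Adam at initial learning rate 5e-4, early stopping on the
validation total loss (patience 10, min-delta 1e-4, defaults chosen as
conventional values) with best-epoch weight restoration; maximum 200 epochs
by default. The validation split takes a stage-stratified 20 % of the
healthy patches. Validation passes use the deterministic eps = 0 path so
the early-stopping signal is noise-free. All randomness (splits, shuffling,
eps draws, weight init) derives from the config seed; a single-threaded run
reproduces its loss history exactly, and two pipeline runs with the same
config produce bit-identical artifacts (checked via manifest checksums).

NaN or infinite losses abort training with the offending epoch and batch
named in the error.

## Synthetic scenes: what they emulate, and what not

The field dataset this method targets (tractor-mounted camera, diffuse
background, green varieties at two growth stages) is not publicly
available, so the package ships a parametric scene generator used by every
test and by the acceptance study.

Emulated: clustered quasi-circular berries (anti-aliased shaded ellipses
with per-berry colour/size jitter and a specular-style highlight) at a
density of roughly 6-10 berries per 130 px window; two colour/size regimes
standing in for the pea-size and pre-harvest growth stages (the late
regime is larger and yellow-green; mean green-channel separation over
berry pixels ~0.1, so a model must learn both regimes); smooth
multiplicative illumination fields (Gaussian-blurred noise, sigma 0.12);
and three damage classes — *discolor* (a connected sub-region covering
20-80 % of one berry shifted to a saturated red-brown, as in rot/sunburn),
*wither* (the same geometry darkened to 35 % with high-frequency texture),
and *stem* (a thin 2-4 px elongated brown structure near the berries).
Damaged scenes default to an expected 50 % of berries carrying a lesion,
mirroring severely damaged bunches. Anomaly masks mark exactly the altered
pixels. Generation is hierarchically seeded (scene index -> substream) and
bit-reproducible.

Not emulated: real bunch geometry and occlusion by leaves or wires,
specular highlights of field illumination, camera noise and motion blur,
red (post-veraison) varieties, and the visual diversity of real disease
symptoms. Passing tests therefore demonstrate that the implementation is
correct and that the method separates clearly visible damage from healthy
tissue under controlled conditions — not field-level performance numbers.

One synthetic-data artifact is worth naming: with dark lesions the BCE
patch score *inverts* — BCE contains the entropy of the target
(`-x log x_hat - (1-x) log(1-x_hat) >= H(x)`), and near-black lesion pixels
have a lower entropy floor than mid-tone healthy berries, so damaged
patches can score *below* healthy ones and the `score > threshold` rule
sits at chance. MSE and l1 are unaffected; the evaluation defaults to MSE.

## Scaled-down acceptance study

`scripts/acceptance.py` runs the complete study at a desk scale chosen to
finish in minutes on one CPU: 160 healthy + 60 damaged scenes of
260 x 260 px (~500 healthy training patches after the 20 % test holdout),
FPL-VAE trained for at most 20 epochs with the deterministic random
extractor, a balanced held-out test set of >= 100 patches per class, an
untrained-twin control, and heatmap localization on 20 further damaged
scenes scored against a 1000-draw permutation null (random same-size pixel
sets within the covered area; the hit count of such a draw is exactly
hypergeometric, which is how the null is sampled). Reported quantities are
computed fresh on every invocation from the supplied seed.

## Numerical choices and degenerate inputs

- float32 weights and activations (float64 for loss accumulation and all
  pixel metrics); single-threaded BLAS keeps runs deterministic.
- BCE clamping epsilon 1e-7; KL asserts finiteness of its inputs.
- Empty scenes (berry count 0) render background + illumination only;
  lesion injection on a berry-free scene is a precondition error, stem
  injection is not.
- A score set containing a single class is rejected by the threshold
  optimizer (accuracy would be degenerate).
- Equal-score ties: threshold candidates are midpoints of *unique* scores,
  ties in accuracy resolve to the smallest threshold.
- Histogram bins are shared between classes; degenerate all-equal scores
  occupy a single bin.

## Known limitations

- Berry-boundary pixels inflate reconstruction error for healthy patches
  (the ROI border artifact); the small-blob post-filter mitigates but does
  not remove it. Observable on synthetic bunches as elevated heat at mask
  borders.
- The colour-threshold segmenter is synthetic-only; real imagery needs an
  external berry segmentation model.
- The random-CNN extractor is weaker than pretrained VGG features; with
  VGG19 weights supplied, separation margins should improve.
- Accuracy on the synthetic study is bounded from above by the
  reconstruction quality of *healthy* berry texture: patch scores correlate
  strongly (~0.8) with berry coverage, so densely covered healthy patches
  are the dominant false positives, while large lesions (over ~1500 source
  pixels) are detected almost perfectly. Neither a wider random extractor
  nor doubling the epoch budget changes this; it is the patch-level face of
  the border/texture artifact above. Desk-scale accuracies (~0.7) are
  therefore not comparable to accuracies obtainable with longer training on
  real field data.
- The untrained-twin control is itself well above the 0.5 majority
  baseline on synthetic scenes (its near-constant output turns the MSE
  score into a colour-deviation detector), so the trained-vs-untrained
  margin at desk scale is modest and seed-dependent; the separation
  statistics (median ratio ~2, rank-test p < 1e-5) are the robust signal.
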