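# Methods

This document describes the algorithms implemented in `cortexfuse`. The
package addresses intraoperative brain-tumor segmentation from hyperspectral
imaging (HSI) in two stages: (1) weakly supervised segmentation of the
exposed brain surface (cortex) and its superficial blood vessels, trained on
RGB images with automatically generated pseudo-labels and transferred to HSI
cubes; and (2) probabilistic fusion of those surface masks with the output
of any 4-class HSI tissue classifier, correcting its characteristic
tumor/vessel confusions.

## 1. Snapshot-mosaic preprocessing (`cortexfuse.preproc`)

The sensor model is a 5×5 snapshot-mosaic camera: 25 narrow NIR bands
(665–960 nm) tile the sensor in a repeating 5×5 filter pattern.

- **Demosaicking.** A raw 1085×2045 frame is rearranged into a band-major
  cube of shape (25, 217, 409); band *b* at output (i, j) is sensor pixel
  (5i + b//5, 5j + b%5). `mosaic` is the exact inverse.
- **Reflectance calibration.** `(raw − dark) / (white − dark)` per band
  with the divisor clamped at 1e−6, using a matched white/dark reference
  pair.
- **Spectral correction.** An optional 25×25 matrix multiplies each pixel's
  spectral vector (vendor crosstalk correction), applied after calibration.
- **Pseudo-RGB reconstruction.** The red channel is the band nearest
  712.4 nm. Green and blue have no in-range primaries, so they are chosen by
  *second-harmonic matching*: a band's half wavelength (rounded half-up to
  0.1 nm) must fall in the green (495–570 nm) or blue (450–495 nm) interval.
  On the sensor-order wavelength table this selects bands 4, 23 and 20
  (1-based). Each channel is min–max normalized.
- **Normalization.** Per-band min–max statistics are fitted on training
  cubes and applied to all cubes (values clipped to [0, 1]).

## 2. Pseudo-label generation (`cortexfuse.pseudolabel`)

Manual supervision is limited to quick square patch annotations inside the
cortex. Everything else is derived automatically.

- **Cortex refinement.** K-means (k = 12) in CIELab color space clusters
  the image. Clusters intersecting the patch annotation are kept; very dark
  clusters (below the annotation's median lightness) are marked vessel-like.
  Other clusters are absorbed when their centroid is closer than the 60th
  percentile of pairwise distances among the in-annotation non-vessel-like
  centroids. The selected region is spatially propagated from the
  annotation (4-connectivity), then closed with a disk(5) element and
  hole-filled.
- **Contour approximation.** Canny edges (thresholds 0.66/1.33 × median
  Sobel magnitude) are filtered to a band around the refined mask's
  boundary and grown along SLIC superpixel adjacency, yielding a
  contour pseudo-label restricted to plausible cortex-perimeter edges.
- **Vessel detection.** A bank of zero-mean oriented line kernels (12
  orientations, 15° apart, two kernel sizes) is correlated with the
  inverted intensity image (reflect padding); the per-pixel maximum
  response is thresholded at the 0.90 quantile and small components are
  removed. Vessels are dark elongated structures, so high response means
  vessel-like.
- **Negative patches.** For contrastive pre-training, 217-px squares are
  sampled at least 108 px (Chebyshev) away from any positive annotation,
  non-overlapping.
- **Adjusted ground truth (HSI path).** Sparse 4-class labels (healthy,
  tumor, vessel, dura) are densified by per-class morphological closing
  (conflicting claims become unlabeled; original labels always survive).
  The *inner* region is the filled concave hull of all cortical labels,
  the *outer* region is dura ∪ background (background = the 8 of 12
  feature clusters most dissimilar from cortical-labeled pixels) minus
  inner, and everything else is *unknown*.
- **Dataset adaptation.** RGB training images are cropped around the
  refined annotation so it fills ≈20 % of an aspect-correct window, then
  resized to the HSI grid aspect.

## 3. Network (`cortexfuse.network`)

`CortexNet` is a dual-input encoder–decoder with a weight-shared trunk:

- **HSI stem:** three *valid* 3×3 convolutions (25→16→8→3 channels, each
  with BN + leaky ReLU); the input is reflect-padded by 3 so spatial size
  is preserved. Its 3-channel output feeds the same trunk as an RGB image.
- **RGB stem:** three 3×3 convolutions (first with stride 2).
- **Encoder:** 14 residual blocks in three stages (4, 4, 6); two-conv
  residual blocks with an average-pool + 1×1-conv + BN downsampling
  shortcut. Total downsampling ×8.
- **Decoder:** three stages of ×2 nearest upsampling, a 1×1-projection
  skip-add from the matching encoder stage, and two 3×3 conv-BN-LReLU
  blocks.
- **Heads:** a 1×1-conv → BN → LReLU → 1×1-conv head produces two logits
  per pixel; a sigmoid yields independent cortex and vessel probabilities.
  A projection head (global average pool → 256→256 MLP, L2-normalized)
  serves contrastive pre-training.
- **Checkpoints** are NPZ archives with named weight groups
  (hsi_stem, rgb_stem, encoder, decoder, head, projection), so the trunk
  can be transferred independently of the HSI stem.

Everything runs on a small reverse-mode autograd engine (`cortexfuse.nn`)
written on NumPy; no GPU framework is required.

## 4. Losses (`cortexfuse.losses`)

RGB training minimizes the unweighted sum of six terms:

1. **L_ctx** — (1 − soft Dice) + BCE of the cortex probability against the
   refined cortex pseudo-label.
2. **L_self-hull** — 1 − soft Dice between the cortex prediction and the
   filled concave hull of its own binarization (penalizes holes and
   fragmentation).
3. **L_cont** — BCE between the prediction's extracted contour (Canny +
   3×3 elliptical dilation) and the contour pseudo-labels, evaluated at
   pseudo-label pixels; gradients flow through the soft boundary-likelihood
   4p(1−p) (straight-through).
4. **L_vsl** — Dice + BCE of the vessel probability against the vessel
   pseudo-label.
5. **L_cross-hull** — 1 − Dice between the filled hulls of the cortex and
   vessel binarizations (vessels should spread across the cortex);
   straight-through gradient via symmetric soft Dice against the other
   head's hull.
6. **L_excess** — ln(α · Dice(1 − Y, Ŷ) + 1) with α = 10: penalizes vessel
   probability mass *outside* the cortex annotation. Exactly 0 for nested
   masks and ln(11) ≈ 2.3979 for complementary masks.

HSI fine-tuning uses masked BCEs: cortex target 1 on inner, 0 on outer,
unknown pixels excluded exactly; vessel target equals the vessel
pseudo-label on inner pixels and 0 on outer. An optional equivariance term
penalizes output changes under horizontal/vertical flips and 180° rotation.
Contrastive pre-training uses the supervised-contrastive (SupCon) loss,
out-view anchor formulation, temperature 0.1.

## 5. Three-step training (`cortexfuse.training`)

Patients are split 70/10/20 (train/val/test); the test fifth
(floor(0.20 n)) is fixed across folds, and train/val are re-drawn per fold
(67 patients → 47/7/13; 70 → 49/7/14).

1. **Step 1 — contrastive pre-training** (400 epochs, batch 128 with
   round(128/3) = 43 cortex positives): SupCon on patch embeddings.
2. **Step 2 — RGB training** (1000 epochs, batch 8): the six-term loss on
   pseudo-labeled RGB crops; augmentations are flips, color jitter and
   Gaussian blur (each p = 0.5) plus random resized crops (area 0.2–1.0,
   aspect 0.55–1.3). Model selection every 10 epochs by validation mean of
   cortex and vessel DSC.
3. **Step 3 — HSI fine-tuning** (700 epochs): the HSI stem trains at the
   base learning rate while every other weight group's rate is divided by
   exactly 1e3 (an optimizer parameter-group scale); flips only; selection
   by mean of cortex pixel accuracy (inner ∪ outer) and vessel DSC.

All steps use AdamW with a per-epoch cosine schedule 1e-4 → 1e-5. The desk
profile (12 synthetic scenes, base_channels 8, epochs 30/300/120, faster
cosine range, heavy step-2 augmentation off — `training.step2.augment`)
runs the whole pipeline on one CPU in about ten minutes. Ablation presets:
solo, pretrain+finetune, rgb+finetune, pretrain+rgb, full, full+EV.

## 6. Probability fusion (`cortexfuse.fusion`)

Given any per-pixel 4-class tissue probability map
P_clf = (P_h, P_t, P_v, P_d):

- **Reduction:** Q_clf = softmax([P_h, max(P_t, P_v, P_d)]) collapses the
  three non-healthy classes (dura is discarded from here on). The softmax
  is applied to probabilities as printed, so Q_clf is intentionally
  compressed toward (0.5, 0.5) and should not be read as calibrated.
- **Fusion:** with cortex probability P_ctx and vessel probability P_vsl
  from the network,
  P_out = [Q_h·(1−P_vsl)·P_ctx, Q_nh·(1−P_vsl)·P_ctx, P_vsl·P_ctx, 1−P_ctx]
  over (healthy, tumor, vessel, background). The four channels sum to 1
  (enforced bit-exactly; the vessel channel is exactly P_vsl·P_ctx). The
  class map is the argmax with ties broken toward the lower index.

The effect: vessels confidently detected by the surface network can never
be relabeled tumor by the tissue classifier, and everything outside the
cortex becomes background — which is precisely how the typical
vessel→tumor confusions of spectral classifiers are corrected.

A minimal reference tissue classifier (per-pixel MLP 25→28→40→4 with
softmax, AdamW + cosine 1e-3→1e-4, accuracy-based selection every 10
epochs) is included to exercise the fusion path end to end.

## 7. Evaluation (`cortexfuse.evaluation`)

- **DSC** (percent; both-empty = 100), **ASSD** (mean of the two
  per-boundary mean nearest-boundary distances, 4-connected boundaries,
  Euclidean), **VHR/VER** (vessel hit rate on vessel-labeled pixels /
  vessel mask fraction on healthy+tumor pixels), one-vs-rest **F1** and
  pair-counting **AUC** on labeled pixels, and row-normalized 4×4
  confusion matrices.
- **Aggregation:** per-patient means, reported as mean ± sample standard
  deviation (ddof = 1).
- **Percentile ranking** selects representative images at the 5th/50th/95th
  percentile of a quality metric for qualitative figures.

## 8. Synthetic scenes (`cortexfuse.synthetic`)

Because the clinical HSI data is access-restricted, the test-bed generates
synthetic craniotomy scenes: a smooth cortex blob with Bézier-stroke
vessels and an optional tumor region, rendered both as an RGB image and as
a 25-band cube (per-class spectral signatures + noise) with a consistent
raw mosaic frame, white/dark references, sparse 4-class annotations, and
dense truth masks. A controllable "flawed classifier"
(`generate_flawed_probs`) samples per-pixel predictions from a 4×4
row-stochastic confusion matrix, which makes the fusion correction property
directly testable.
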