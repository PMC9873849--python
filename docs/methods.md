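# Methods

## Setting and model

The pipeline targets multi-label chest-radiograph analysis where only
image-level finding labels are abundant and bounding boxes exist for a small
annotated subset. A staged CNN backbone produces feature maps F^l at
resolution levels l = 2..5 (spatial side = input/2^l). Because stride-32
maps are too coarse for useful localization, Merge Blocks rebuild a
resolution-preserving map coarse-to-fine:

    F_o^5 = F^5,   F_o^l = g(F_o^{l+1}, F^l)

where g: reduce both inputs' channels by 4 (1×1 conv + ReLU), bilinearly
upsample the coarse one ×2, concatenate, and project back to F^l's channel
count (1×1 conv + ReLU). The finest merged level defaults to 2 (stride 4).
The published multi-resolution parameter counts could not be reproduced
analytically from the block description, so the finest level is a
configuration knob and only the two standard-model counts are treated as
exact references; both are reproduced to the digit (ResNet50 + 14-way head:
23,536,718; EfficientNetB4 + 14-way head: 17,573,718; 1×1 classifier with
bias included). EfficientNetB4 follows the standard compound-scaled MBConv
plan (width 1.4, depth 1.8, squeeze-excitation on block input channels / 4)
and is provided for architecture/parameter parity; no pretrained weights are
shipped for any base, and on synthetic data all training starts from random
initialization.

## Classification head and CAMs

The classifier is one affine map from channel space to class space, applied
per pixel (a 1×1 convolution): CAM_c(i,j) = w_c·F_o(:,i,j) + b_c. Class
scores are LSE pools of each class map,

    z_c = (1/γ)·log( mean_ij exp(γ·CAM_c(i,j)) ),  γ = 10,

computed with a max shift (the shift provably does not change the gradient).
LSE interpolates between mean (γ→0) and max pooling (γ→∞), so per channel
mean ≤ LSE ≤ max. **Order decision:** the source description admits both
"pool features then classify" and "classify per pixel then pool the maps";
the two disagree because LSE is nonlinear. We classify-then-pool, which
makes `lse_pool(CAM_c) = z_c` an exact identity (asserted on random
instances) and keeps the CAM and score paths sharing every weight. Both
orders coincide on constant maps.

**Non-maximum suppression.** Before refinement, activations are clipped at
zero and, at each pixel, only the strongest class keeps its value (ties to
the lowest class index). The zero-clip makes the operation idempotent
(without it, a suppressed pixel whose winner is negative would change class
on a second pass) and matches the foreground semantics of attention-style
refinement. The alternative reading — spatial suppression within each class
map — is not implemented.

## Pixel correlation module

Refinement is a row-stochastic self-attention average over the suppressed
CAM:

    y_i = (1/C(x_i)) Σ_j ReLU(cos(θx_i, θx_j)) ŷ_j,
    C(x_i) = Σ_j ReLU(cos(θx_i, θx_j)),

with θ a 1×1 linear embedding (no bias, no activation) of the finest
resolution-preserving feature map — the single-map choice is configurable;
the cited attention construction concatenates several levels, but the
description here names only the backbone output. Defining C as the row sum
of the rectified cosines is the only normalization that makes "weighted
average" exact, which yields the convexity guarantee min ŷ ≤ y_i ≤ max ŷ
(tested per class on random instances). Embedding width defaults to a
quarter of the input channels. Numerical guards: norms use ε = 1e-8; a row
whose rectified similarities vanish (possible only for an exactly zero
embedding) falls back to the identity row, keeping W row-stochastic.

## Losses

- **Class-balanced BCE** (phase 1): per batch, β_P^c = (|P_c|+|N_c|)/|P_c|,
  β_N^c = (|P_c|+|N_c|)/|N_c| (so 1/β_P + 1/β_N = 1 when both counts are
  positive); a zero count sets its weight to 0 since the corresponding term
  vanishes identically. The per-sample class sums are averaged over the
  batch — the per-sample form leaves the batch reduction open, and the mean
  keeps the learning rate batch-size-invariant. Probabilities are clamped at
  1e-7 inside the logs.
- **Multi-label soft margin** (phase 2): mean over samples and classes of
  y·log(1+e^{−z}) + (1−y)·log(1+e^{z}), computed with a stable softplus; z
  comes from global average pooling of the refined maps of both Siamese
  branches (the two branch losses are averaged).
- **Equivariant cross regularization with OHEM**: the per-pixel L1 terms
  |A(y^o) − ŷ^t| and |A(ŷ^o) − y^t| are each reduced by keeping the top
  20 % of (class × pixel) elements (count = ceil(fraction·N), kept elements
  averaged, selection computed on current values without gradient), then the
  two reductions are **added**. One printed form of this objective has a
  minus between the norms; a difference of absolute values is unbounded
  below and contradicts the consistency construction the loss derives from,
  so we treat the minus as an erratum and use the sum. Pixels a rotation
  pulls in from outside the frame are masked out before selection.
- **Combined objective**: 1.5·MSML + 1.0·ECR.

## Two-phase schedule

Phase 1 (Adam, betas (0.9, 0.9), defaults lr 3e-4, 35 epochs, micro-batch 32
with 3 gradient-accumulation steps → effective batch 96) trains backbone and
classifier; earlier backbone stages can be frozen (the reference
configuration trains only the third and fourth residual stages when starting
from pretrained weights). Accumulation scales each micro-batch loss by
1/steps, so an update equals a single step on the concatenated batch — an
exact identity for batch-mean losses, verified on a linear model.

Phase 2 (Adam, default lr 1e-6, 3 epochs) trains **only** θ. Per image a
rotation angle is drawn uniformly in ±30°; flips are never sampled. One
Siamese pass computes CAMs of the rotated image and, separately, CAMs of the
original to be rotated inside the loss; rotation of CAMs uses the same
bilinear/zero-fill resampling as images and is differentiable. Because the
backbone is frozen and the score path bypasses the PCM, classification
probabilities are bit-identical across phase 2 — asserted, not assumed.
Batch-norm runs on its running statistics in phase 2 (frozen backbone).

## Synthetic data generator

The generator emulates the structure of the real collection — PNG grayscale
images, pipe-separated multi-label table, a bounding-box table covering a
subset of images, patient-level split lists — with geometric lesion classes
(disk, ring, bar) on a smooth low-frequency background plus Gaussian noise
(sd 0.05), intensity 0.6, sizes 10–18 px on a 64 px frame, 25 % of images
lesion-free, 1–2 lesions per positive class, two images per synthetic
patient. A configurable fraction of positive images can keep labels but drop
their boxes, mirroring sparse annotation (default 0: every positive is
box-annotated, which the localization tests rely on). It does **not**
emulate anatomy, pathology appearance, inter-reader ambiguity, label noise,
or the real dataset's scale, so passing the synthetic experiment shows the
*mechanics* recover known signal — not clinical performance.

## Scaled-down experiment

`camloc.experiments.run_synthetic_benchmark`: 200 images, 64 px, 3 classes;
patient-level 80:20 train-pool/test split, with a validation subset inside
the pool. Phase 1 runs 5 epochs at lr 3e-3, micro-batch 4, from 6 random
initializations, keeping the restart with the best validation AUC — at this
scale (≈160 optimizer steps) training is initialization-sensitive, and
restart selection on validation data is the standard remedy; the test
patients are never touched. Phase 2 runs 3 epochs at lr 3e-2 on the PCM
embedding (tens of parameters; far larger steps are appropriate than for a
full-scale pretrained backbone). Localization uses Q = 0.7 on 8-bit
heatmaps upsampled to the image frame, 8-connected regions, tight boxes, no
minimum-area filter, IoBB > 0.1 strict. The run takes ~2 minutes on one
CPU. Across seeds the held-out mean AUC is typically 0.87–0.97 and
disk-class Lacc 0.5–1.0 (40 test images make these quantities coarse);
classification drift across phase 2 is exactly 0 for every seed.

## Numerical conventions

- Boxes are (x, y, h, w), 0-based, origin top-left, closed on left/top and
  exclusive on right/bottom; annotations live at original image resolution,
  and predicted boxes produced in the model's input frame are rescaled back
  by the known resize factor before scoring.
- Bounding-box tables are parsed by header name with a positional
  (x, y, h, w) fallback.
- Heatmap quantization: per-map min-max to [0, 1], then round-half-to-even
  to [0, 255]; a constant map (no localization signal) maps to all zeros.
- Bilinear resizing uses half-pixel centers without corner alignment and
  edge replication; rotation uses zero fill plus a validity mask.
- Grayscale images are replicated to 3 channels and normalized with the
  ImageNet channel statistics before entering any backbone.
- Determinism: every stochastic component takes a seed and uses an isolated
  numpy generator; repeated runs are bit-identical.

## Known limitations

- The FPN denominator is the number of ground-truth-bearing images per
  class (the convention of the benchmark this protocol follows); evaluating
  false positives on images without ground truth for the class would need a
  different scope rule, which the protocol leaves unspecified.
- EfficientNetB4 forward passes are supported by the layer toolkit but
  untrained/unpretrained; the architecture exists chiefly for parameter
  parity.
- The numpy toolkit is single-threaded and CPU-bound; it is sized for the
  desk-scale experiments here, not for the 112k-image full-scale study.
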