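# Methods

## Problem and model

`sdhseg` trains binary tumor-segmentation networks with a boundary-aware
objective. Given a predicted boundary point set P and a ground-truth
boundary point set G on the pixel grid, the core quantity is the averaged
(bidirectional mean-of-minimum) Hausdorff distance

    H(P, G) = (1/|P|) Σ_i min_j ||p_i − g_j||₂ + (1/|G|) Σ_j min_i ||g_j − p_i||₂

in pixel units. Unlike the classical worst-case Hausdorff distance
(max-of-min, available here as a diagnostic, `hausdorff_max`), the averaged
form is robust to single outlier points and decomposes into per-point
terms whose subgradients exist everywhere. The training objective mixes
this boundary term with pixel-wise binary cross-entropy,

    L = λ₁ L_BCE + λ₂ L_SDHL,   defaults λ₁ = 0.6, λ₂ = 0.4,

so region accuracy (BCE) and boundary alignment (the distance term) are
traded explicitly.

## Boundary geometry

A *boundary point* is a foreground pixel with at least one background
pixel among its 8 neighbours, the frame exterior counting as background
(equivalently: mask minus its 3×3 erosion). This guarantees every
non-empty mask has a non-empty boundary. Coordinates are 0-based
(row, col); distances are exact Euclidean. Distance fields use the exact
Euclidean distance transform (`scipy.ndimage.distance_transform_edt`),
not a chamfer approximation.

Empty-set convention: if exactly one of the two boundary sets is empty,
both directed terms saturate to the image diagonal √(H²+W²) — a finite,
maximal, shape-scaled penalty that keeps the loss defined for
all-background predictions; if both are empty the loss is 0.

## Subgradients

Away from nearest-neighbour ties, the loss differentiates per point to

    ∂H/∂p_i = (1/|P|) (p_i − g_k)/||p_i − g_k||,

with g_k the nearest ground-truth point (and symmetrically for g_j through
its nearest p_l). At ties any nearest neighbour yields a valid
subgradient; ties are broken deterministically towards the lowest index in
row-major order so runs are reproducible. At coincident points the zero
vector is returned (a valid subgradient of the Euclidean norm at 0),
keeping updates bounded.

Note that this per-point expression follows a point's own directed term;
when p_i additionally attains the reverse minimum for some g_j, the full
derivative of H carries an extra (1/|G|)(p_i − g_j)/||·|| contribution.
The finite-difference tests verify both the reported expression (on points
that attain no reverse minimum) and the full decomposition.

## Differentiable training surrogate

Discrete boundary extraction gives no differentiable path from network
parameters to boundary-point coordinates, so training uses a pixel-grid
surrogate anchored to the point-set loss. With p = σ(logits):

* soft boundary  s_b = p · (1 − minpool₃ₓ₃(p)), zero-padded min pooling so
  the frame exterior acts as background. On hard 0/1 maps s_b is *exactly*
  the 8-connected boundary indicator.
* forward term: the s_b-weighted mean of the ground-truth boundary's
  distance field, blended with the saturation constant as
  min(S,1)·⟨s_b,D_G⟩/max(S,ε) + (1−min(S,1))·diag, S = Σ s_b, ε = 1e−9.
  The blend is exact on hard masks (S is then an integer ≥ 1, or 0) and
  keeps gradients bounded as S → 0 instead of exploding like 1/ε.
* reverse term: the mean of the thresholded prediction's distance field
  over the ground-truth boundary, treated as a non-differentiable
  constant. Gradients therefore flow only through s_b.

The anchoring contract — on hard 0/1-equivalent logits the surrogate
equals the point-set loss, saturation cases included — is what ties the
surrogate to the loss it stands in for; it holds to ~1e−13 in float64. A
simpler soft-boundary choice, |p − meanpool₃ₓₓ(p)|, was rejected because
it is not binary on hard masks (inner boundary pixels score k/9, *outer*
background neighbours m/9), which breaks the anchoring contract.

The prediction threshold is σ(logits) > 0.5 (logit > 0) everywhere.

### Scale of the boundary term

The point-set loss is kept in raw pixel units by default. For *training*,
the surrogate is normalised by the image diagonal
(`normalize_sdhl=True` in `TrainConfig`/`UNetSegmenter`): in raw units the
boundary term is O(diagonal) ≈ 90 px at 64×64 while BCE is O(1) nats, so
with λ = 0.6/0.4 the boundary term would dominate the descent direction by
two orders of magnitude and the stated weights would be meaningless.
Normalised, both components are O(1) and the λ mix behaves as intended.

The max-form HDL surrogate replaces the weighted mean by the maximum of
s_b ⊙ D_G per direction; it equals the classical worst-case Hausdorff
distance on hard masks and serves as the ablation baseline only.

## Metrics

Accuracy, precision, recall, Dice (count form 2TP/(2TP+FP+FN), equal to
the set form), F1, IoU and Matthews correlation from pixel confusion
counts. Zero denominators return 0 with a logged warning; the both-empty
Dice convention is 1. Two aggregations are reported side by side because
they answer different questions on imbalanced data:

* micro-averaged (pixel counts pooled over the set) — dominated by large
  lesions;
* per-image mean of overlap scores with the both-empty = 1 convention —
  a clean rejection of a tumor-free image counts as perfect rather than
  as an undefined 0/0 (the count-form 0 convention would cap the mean at
  the positive-class prevalence on mostly-negative data).

## Networks

Three encoder–decoder architectures at configurable depth/width, built on
a small in-package reverse-mode autodiff engine (numpy, im2col/BLAS
convolutions): plain UNet (double conv–batchnorm–ReLU blocks, 2×2
max-pool, nearest-neighbour upsampling + conv, skip concatenation),
Attention UNet (additive attention gates, σ(ψ(ReLU(W_g g + W_x x))),
reweighting each skip), and UNet++ (nested dense skip pathways). Final
1×1 convolution emits a single-channel logit map; He initialisation;
dropout (default 0.1) after each double-conv block in training mode.
"U-Net+" and 2-D "V-Net" are accepted as config aliases mapping to `unet`
with a warning, as no defining topology exists for them. `depth` is the
number of pooling steps, so inputs must be divisible by 2^depth.

## Optimisation and training loop

Adam is implemented from its defining updates (β₁ = 0.9, β₂ = 0.999,
ε = 1e−8, bias-corrected moments) and unit-tested against hand-evaluated
traces; the trainer applies exactly this function per parameter. Defaults
follow the study configuration: learning rate 1e−3, batch size 32,
dropout 0.1. Per-sample losses are averaged over the batch.

Randomness is split into independent child streams of the run seed
(weight init, per-epoch shuffling, augmentation, dropout), so disabling
one consumer does not perturb the others and training is bit-reproducible
for a fixed seed on a fixed platform. Augmentation: resize to the
configured size, multiplicative contrast in [0.8, 1.2] and additive
brightness in [−0.2, 0.2] on the image only (mild, standard
medical-imaging jitter; clipped to [0,1]), then independent horizontal and
vertical flips with probability 0.5 applied identically to image and mask.

Validation Dice (per-image mean) is computed each epoch; the best
checkpoint is retained and early stopping triggers after a 10-epoch
plateau. Desk-scale default is 30 epochs (the full-scale study
configuration uses 200); both are configurable.

## Synthetic phantoms

The generator emulates the statistical structure of single-slice
low-grade-glioma FLAIR data: an elliptical "skull" filled with smooth
low-frequency tissue texture over a dark exterior; for tumor-positive
samples, 1–2 irregular lesions (harmonically deformed ellipses) totalling
1–10% of the frame. Lesions are brighter than the surrounding tissue but
their margins are genuinely blurred — the brightness bump ramps from ~0
at the support edge to its maximum over ~4 px and is lightly smoothed —
so edge pixels are ambiguous in intensity while the mask remains the
exact lesion support. This preserves the two challenges the loss targets:
strong class imbalance (34.9% of samples positive by default, matching
the study data; 70/20/10 stratified train/test/validation split) and
boundary ambiguity. Everything is a pure function of the seed.

What the phantoms do *not* model: MRI physics (bias fields, Rician
noise), multi-modal stacks, anatomy, inter-scanner variation. Passing
tests on phantoms therefore demonstrate the correctness and the
qualitative behaviour of the losses and trainers at desk scale, not
clinical performance.

## Problem sizes and numerical choices

Desk-scale experiments use 200 phantoms at 64×64, attention UNet with
depth 3 and 8 base channels, 30 epochs — small enough to train on one CPU
core in minutes while still exercising every component end to end.
Networks compute in float32; the loss oracles, gradient checks and the
anchoring contract run in float64. Surrogate saturation ε = 1e−9;
batch-norm ε = 1e−5, momentum 0.1. Nearest-neighbour and pooling ties
resolve to the first (lowest-index) candidate.

## What the desk-scale comparison can and cannot show

The matched-seed comparison run by `scripts/acceptance.py` (SDHL+BCE vs.
BCE-only, 200 phantoms, 30 epochs) demonstrates learnability — both arms
reach held-out per-image Dice ≈ 0.96 — and computes the mean boundary
distance of each arm. On these phantoms both objectives drive the
boundary error to a sub-pixel noise floor (≈ 0.3–0.5 px, most test images
exact ties at 0), and the paired difference between the arms is an order
of magnitude smaller than its seed-to-seed spread with either sign
occurring. The desk-scale phantom task therefore does not resolve a
boundary-quality ordering between the two objectives; demonstrating the
boundary term's benefit requires data whose boundary evidence is
genuinely ambiguous or label-noisy at larger scale, which is outside this
package's hermetic test conditions.

## Known limitations

* The reverse surrogate term is a stop-gradient constant, so missing
  boundary segments are penalised in value but corrected only through the
  BCE term's gradients.
* The averaged Hausdorff term is count-normalised, hence scale-free in
  boundary mass: on tumor-free samples its gradient vanishes (the field
  is constant), and spurious detections there are cleaned up by BCE alone.
* 2-D, single-channel, binary masks only; no anisotropic spacing,
  sub-pixel contours or 3-D volumes.
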