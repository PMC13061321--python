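# Methods

`mvtomo` implements a multi-view, graph-guided transformer for voxel-level
segmentation of cryo-electron tomography (cryo-ET) volumes, together with
the synthetic data, training objectives, inference and evaluation machinery
needed to exercise the method end to end on one CPU.  This note records the
model, the choices made where the design was genuinely open, and what the
desk-scale experiments do and do not demonstrate.

## Problem setting

A tomogram is a 3D grayscale voxel grid `x ∈ R^{H×W×D}`; the goal is a
voxel-wise class label `y ∈ {0..N}^{H×W×D}` (0 = background) marking each
macromolecular particle.  Large tomograms are cut into cubic patches
(32³ by default) and each patch is segmented independently; at inference
the patches overlap by 50 % and per-class probabilities are blended with a
smooth window.

## Model

**Multi-view tokenization.**  Each patch is observed along three
orthogonal perspectives: the canonical XY frame, the YZ frame
(axes reordered to `(H, D, W)`) and the XZ frame (`(D, W, H)`).  Both
reorderings are involutive axis permutations, so realignment back to the
canonical grid is exact.  In each frame the volume is split into `Hp³`
cubic patches (4³ default), giving `L = (H/Hp)(W/Wp)(D/Dp)` tokens in
row-major lattice order.  A single linear projection (shared by all
views) maps each flattened patch to `C` channels; each view then adds its
*own* learnable position table, so view identity is carried entirely by
the position embeddings.  Note that the three views tile the volume into
the *same* set of cubes — what differs is the traversal order and hence
the positional geometry the attention layers see.

**Context encoder and visual graph.**  In parallel, three stride-2
conv(3³)–BatchNorm–ReLU blocks map the canonical patch to a `C`-channel
feature grid (4³ for a 32³ input, i.e. N = 64 feature vectors).  Lloyd's
k-means clusters the flattened features into `K` nodes (K = 16 default):

* init: seeded farthest-point selection;
* assignment: nearest center by squared distance, ties to the smallest
  cluster index;
* empty clusters are repaired by granting each its own farthest point,
  never taking a donor cluster's last member (this also covers degenerate
  duplicate-feature inputs, which do occur after ReLU);
* stop on relative objective improvement < 1e-4 or 20 iterations.

The node vectors are the cluster means.  Clustering runs inside every
forward pass and is treated as non-differentiable; gradients reach the
context encoder through the cluster-mean computation with assignments
detached.

**Graph-guided encoder.**  The encoder is a pre-norm ViT stack (`Ln`
layers, `C` channels, `heads` heads; 12/256/16 default), shared across
views.  Its first layer uses the K graph nodes as attention queries
against the layer-normalized tokens, producing K node summaries.  A
K-sequence cannot be added residually to L tokens, so the summaries are
redistributed: the transpose of the attention logits is renormalized over
the node axis (an L×K softmax) and each token receives a convex
combination of the per-head summaries, added residually to the raw
tokens.  The redistribution is isolated in one function so alternative
readings can be swapped.  Layers 2..Ln are standard pre-norm
self-attention + MLP blocks (expansion 4, GELU, no dropout).

**Decoders.**  Two interchangeable heads produce `(N+1)`-channel logits
at full resolution:

* **MF** (multi-level fusion) taps `n_tap` evenly spaced encoder layers.
  Each branch applies conv–BN–ReLU at lattice resolution (narrowing
  `C → C/4`), one trilinear ×Hp upsampling, then a second conv–BN–ReLU at
  voxel resolution; branches are concatenated and reduced by a 1×1×1
  head.  Placing the second convolution *after* the upsampling is a
  deliberate choice: with both convolutions at lattice resolution no
  kernel ever sees voxel-scale structure and the head can only emit
  trilinearly-smooth fields, which caps boundary accuracy well below what
  the same budget achieves with voxel-resolution refinement.  The `C/4`
  narrowing keeps the voxel-resolution convolutions affordable; the
  ordering is configurable (`upsample_at = pre|mid|post`).
* **P3DA** (parallel 3D atrous) trilinearly upsamples the final layer's
  features to full resolution and runs four parallel branches — a 1×1×1
  conv and 3³ convs at dilation 6, 12, 18 — each with BN+ReLU, then
  concatenates and reduces with two 1×1×1 convs.  Dilated convs use zero
  'same' padding.

Per-view logits are realigned to the canonical grid (spatial axes only)
and fused by element-wise summation.

**View-masked self-supervision (VSL).**  Each step masks one uniformly
chosen view at token rate η (0.5 default): masked tokens are replaced by
a learned mask token plus that view's position embedding.  A lightweight
2-layer transformer decoder attends over the concatenated three-view
encoder output and regresses the raw voxel contents of the masked
patches; the loss is the MSE over masked patches only.  Because the three
views are permutations of the same noisy volume, the masked content is in
principle recoverable from the unmasked views up to the information lost
in the 64→C patch projection; the task trains cross-view correspondence.
During joint training the segmentation pass runs unmasked and one extra
masked encode of the chosen view feeds the reconstruction loss, so
masking never corrupts the segmentation targets.

## Objective and optimization

The training loss is the unweighted sum of voxel-mean cross-entropy on
the three realigned per-view predictions, cross-entropy on the fused
prediction, and the reconstruction MSE when VSL is enabled.  Adam with
initial learning rate 1e-3, multiplied by 0.1 every 100 epochs, batch 72,
200 epochs at full scale.  Three pieces of optimization hygiene are part
of `train()`:

* the decoder head bias is initialized to the log class priors of the
  training labels (background dominates; without this the first part of
  a short run is spent learning the marginal class distribution);
* a bias-corrected Polyak average (decay 0.99) of the weights is taken as
  the final model;
* batch-norm statistics are re-estimated with full passes over the
  training set after the last step — running averages from batch-8
  minibatches are noisy estimates and measurably miscalibrate evaluation;
* gradients are clipped to global norm 5 (reconstruction-only training on
  heavy-noise targets otherwise diverges).

## Synthetic data

The generator emulates the statistical regime the method assumes, not the
biology: cubic patches containing a few non-overlapping solid ellipsoids
(class-specific mean intensity against zero background), additive
Gaussian noise at a controlled signal-to-noise ratio, and optionally a
Fourier-space missing wedge.  **SNR is the variance ratio
var(signal)/var(noise)** — stated prominently because amplitude-ratio and
dB conventions also circulate.  The missing wedge zeroes the unsampled
double wedge of a ±halfangle single-axis tilt about the W axis; on a
discrete grid each coefficient is attributed the angle of its inner cell
edge so the operator converges to the identity as halfangle → 90°.
Particles are placed largest-first with full-configuration restarts on
failure; genuinely infeasible configurations raise a capacity error.

What the generator does *not* model: protein density maps, the contrast
transfer function, reconstruction artifacts, crowding, membranes and
filaments.  Passing tests therefore demonstrate that the architecture,
objectives and pipeline work as specified and can learn shape-from-noise
at realistic SNR — not that the model reaches any particular accuracy on
real tomograms.

## Desk-scale study conditions

All scaled-down experiments (tests and `scripts/acceptance.py`) share one
frozen configuration: 16³ patches, one foreground class, 1–2 particles of
radius 2.5–4.0 voxels (the largest radii for which non-overlapping
placement of two particles in a 16³ box is geometrically feasible), SNR
0.05; 200 training and 32 held-out patches; toy model (Ln = 2, C = 32,
4 heads, K = 4, patch 4³, MF decoder); 300 Adam steps at batch 8,
learning rate 1e-3.  The toy segmentation study optimizes the
segmentation objective only; masked-view reconstruction is studied
separately (200 reconstruction-only steps against a constant
mean-predictor baseline).

Two empirical notes on these conditions.  First, at radius ~3 voxels a
one-voxel boundary shell is a large fraction of the particle volume, so
voxel-level Dice at SNR 0.05 saturates in the mid-0.8s for *any* method:
`scripts/acceptance.py` computes, on the same held-out set, a
matched-filter oracle (Gaussian smoothing and threshold both tuned on
the ground truth) that the trained model exceeds.  The residual gap to a
perfect mask is boundary-voxel noise intrinsic to the data, not model
error.  Second, 200 reconstruction-only steps only begin to learn the
cross-view correspondence, so the VSL improvement over the mean baseline
is real but small at this scale.

## Numerical choices

* All network arithmetic is float32 on a compact numpy reverse-mode
  autodiff engine written for this package; convolutions pick between an
  im2col GEMM (small outputs) and shifted-slice accumulation (large
  outputs) on a size threshold.
* Trilinear upsampling uses half-voxel-aligned, edge-clamped
  interpolation matrices applied axis-wise.
* The blending window is a separable raised cosine normalized to 1 at the
  center and floored at 1e-3 so border voxels keep nonzero weight; with
  it, overlap-tiled constant fields are reproduced exactly (partition of
  unity).
* Tiling shifts the final patch per axis inward so no patch exceeds the
  volume; with zero overlap, non-divisible extents are zero-padded and
  the padding cropped after fusion.
* k-means ties break toward the smallest cluster index; determinism
  everywhere is by explicit integer seeds.
* Checkpoints are plain `.npz` archives of named parameters and buffers;
  save → load → predict is bitwise-reproducible.

## Known limitations

* The full-scale profile (512³ tomograms, Ln = 12, C = 256) is
  implemented and shape-tested but not trained here; throughput on one
  CPU makes full training impractical by design.
* The guided layer's redistribution step is one defensible reading of a
  type-ambiguous construction; alternatives (node tokens appended to the
  sequence; broadcast addition of summaries) are not implemented.
* Whether the context encoder's channel width must equal the
  transformer's is assumed yes (required for query/key compatibility).
* The reconstruction decoder regresses raw voxel intensities; no
  per-patch target normalization is applied.
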