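# Methods

This note records the model, the procedural data generator, the numerical
choices and the known limits of what the test suite demonstrates.

## Network

The segmentation model is a four-level U-shaped encoder–decoder over NCHW
float64 tensors. Encoder level k (k = 1..4) applies two
`ReLU(BN(conv3x3))` units at width w·2^(k−1) followed by 2×2 max-pooling;
the bottleneck applies two more units at width 16w. Input patches must be
divisible by 2⁴ = 16. The decoder mirrors the encoder with transpose-conv
(kernel 2, stride 2) upsampling. The default base width is w = 32
(doubling per level); the full variant then counts ~23.2 M parameters —
the width is a configuration knob, and the parameter count is reported by
`count_parameters`, not targeted.

Three optional blocks (the five ablation variants toggle them):

**RASF** (bottleneck). Branches F₁, F₂, F₃ from dilated 3×3 convolutions
with rates (1, 3, 5) and padding equal to the dilation, so all branches
share the input's spatial size. Fusion: F₁₂ = F₁ + F₂ and F₂₃ = F₂ ⊙ F₃
elementwise; F₁₂₂ = ReLU(BN(conv3×3(F₁₂))); a channel-attention gate
(GAP → FC(C→C/r) → ReLU → FC(C/r→C) → sigmoid, r = 16 by default — the
conventional squeeze–excitation reduction) re-weights F₁; softmax over the
*channel* axis of F₂₃ (per spatial location) re-weights F₃. The two gated
maps are concatenated (a summed alternative is config-switchable) and
reduced by a plain linear 3×3 convolution before the residual addition.
Ending the branch with an un-normalized convolution makes the
zero-weight block exactly the identity — a deliberate property used as a
regression test. The elementwise product for F₂₃ (rather than
concatenation) follows the block's defining equations.

**AFF** (skip connections). For decoder level k, `low1` is the tensor
entering encoder level k (the input image for k = 1, the pooled map
otherwise), `low2` is encoder level k's conv output, `high` the decoder
feature one level below. Because the gate is produced by global average
pooling, `low1` and `low2` may differ spatially; the 3×3 projection conv
maps `low1` to `low2`'s channel count so the gate broadcasts. The gated
map is L2-normalized across channels at each pixel with ε = 1e-8 inside
the square root (smooth at the origin). Output =
concat(low2, normalized gate map, BN+ReLU(transpose-conv(high))), giving
3·C_k channels into the decoder convs (2·C_k for the vanilla variant).

**MPF** (head). Decoder outputs at full, 1/2 and 1/4 resolution are
bilinearly upsampled (half-pixel-centre convention, separable
interpolation matrices) to full resolution and convolved to a common
width (= w). The gate is ReLU(GAP(softmax(X₁ ⊙ X₂))) — ReLU being the
convention used for this block's activation, with L2 normalization
available as a switch — broadcast over space and multiplied into the
convolved finest path. Without MPF the head consumes the finest decoder
output directly. The final head is always 1×1 conv + sigmoid.

All convolutions are followed by BN+ReLU except where a block's own
activation (sigmoid, softmax, L2-norm) or the linear residual reduction
applies.

## Tensor engine

No GPU framework is used: `sfanet.nn` is a small tape-based reverse-mode
autodiff engine on numpy (stride-1 dilated conv2d via strided im2col
views, the exact kernel-2/stride-2 transpose convolution as a single
einsum, 2×2 max-pooling with first-winner tie-breaking, bilinear
upsampling as separable linear operators, batch norm with running
statistics, linear layers, sigmoid/softmax/ReLU/L2-norm, Adam with
classic L2 weight decay folded into the gradient). Every operation is
checked against central-difference gradients at 1e-5 in the test suite.
Float64 throughout; computation is single-threaded numpy and therefore
bitwise deterministic for fixed seeds.

## Training protocol

Random 96×96 patches (size configurable) are drawn uniformly over samples
and positions; patch and label windows are cut identically, and a window
re-cut oracle asserts alignment. Patch centres are not restricted to the
FOV by default (an `fov_only` flag exists). Each image is normalized to
zero mean / unit variance over FOV pixels before patching (switchable);
some normalization is needed for stable training and this is the recorded
choice. The patch pool splits 80/20 into train/validation
(round(n·f) / remainder — 190,000 → 152,000/38,000). Optimization is Adam
with lr 1e-4, weight decay 1e-4, batch 16; predictions are clamped to
[1e-7, 1−1e-7] inside the cross entropy, which is undefined at 0 and 1.
No learning-rate schedule and no early stopping beyond keeping the
best-validation-loss checkpoint. The epoch count is user-set; the
synthetic integration test uses 5. Leave-one-out folds are provided for
small datasets.

Inference tiles each image with stride P/2 by default (clamped last
windows guarantee edge coverage) and averages overlapping predictions;
`reconstruct∘tile` is the exact identity for consistent predictions.

## Evaluation

Confusion counts binarize at `prob ≥ threshold` (default 0.5; ties count
positive) over FOV pixels only; an all-pixels mode exists because the
masking convention differs between studies. SE = TP/(TP+FN),
SP = TN/(FP+TN), ACC = (TP+TN)/total; zero denominators raise an explicit
`UndefinedMetricError` rather than silently returning 0. The ROC sweep
runs over the distinct score values with a +∞ sentinel; the trapezoidal
area equals the tie-aware Mann–Whitney statistic (asserted to 1e-10
against a brute-force pairwise count, and cross-checked against
scikit-learn). Metrics are micro-averaged over all evaluated pixels, with
a per-image breakdown attached.

## Synthetic data generator

The generator emulates the gross structure of a fundus photograph: a
circular FOV disk (radius fraction 0.48) on black background; per root, a
random-walk vessel centreline (step 2 px, heading jitter σ = 0.18 rad)
starting near the rim pointing inward; side branches with probability
0.08 per step, child caliber 0.6–0.9 of the parent, caliber tapering
0.985 per step down to a 0.6 px floor, depth-capped at 4. Default
conditions: 128-px images, 4 roots, root widths 1.0–2.5 px, vessel
contrast −0.35 (vessels darker than the 0.55 background, as in real
fundus images), smooth background texture (amplitude 0.05), Gaussian blur
σ = 0.8 px, additive noise σ = 0.03. These defaults put the vessel
fraction at ~10% of the FOV (band 4–20% across seeds), matching typical
retinal vessel density, and guarantee thin low-contrast vessels because
calibers taper below 2 px. The label mask is the exact pre-blur,
pre-noise rasterization: a pixel is vessel iff its centre lies within
width/2 of a segment (the continuum limit of stamping disks along the
centreline).

What the generator does **not** emulate: optic disc and macula, pathology
(exudates, hemorrhages), color (images are grayscale with an optional
3-channel replication), non-uniform illumination, and the camera's
characteristic noise. Passing tests on synthetic data therefore
demonstrate that the pipeline is mechanically correct and that the
network can learn vessel-like curvilinear structure — not that it reaches
any particular accuracy on real fundus photographs.

## Problem sizes and observed behaviour

The integration-scale experiments use reduced settings chosen as the
package's own desk-scale conditions: base width 8, 32-px patches, ~1,000
patches from 20 images, 5 epochs (~300 optimizer steps). Under these
conditions the full variant's held-out stitched pixel-AUC typically
reaches ~0.75 from a ~0.5 untrained start; the same run continued to 15
epochs crosses 0.90, and with Adam's common 1e-3 learning rate it reaches
~0.96 within 5 epochs. The retained lr of 1e-4 is the protocol value,
calibrated for training pools two orders of magnitude larger, so the
short run trades final accuracy for fidelity to the protocol — the
acceptance suite records this gap rather than re-tuning the schedule.
An untrained network's AUC is seed-dependent (its random features may
anti-correlate with vessels); values between ~0.2 and ~0.7 occur across
initialization seeds.

## Known limitations

- Stride-1 convolutions only; downsampling is exclusively max-pooling and
  upsampling is transpose-conv/bilinear, which covers this architecture
  but not general strided networks.
- The transpose convolution is fixed at kernel 2 / stride 2 (exact 2×).
- CPU float64 throughout: correct and deterministic, but far slower than
  a GPU framework; the defaults in the examples are sized accordingly.
- Batch-norm running statistics update in training mode only; very short
  runs evaluate with statistics that lag the batch statistics.
- The exact feature wiring of the fusion blocks into the U-shape follows
  the reading recorded above (AFF's `low1`/`low2` = pre-/post-subsampling
  features of the same level; MPF over the three finest decoder stages);
  other readings of the block diagrams are possible.
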