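# sfanet — retinal vessel segmentation with a U-shaped multiscale-fusion network

Segmenting the retinal vasculature in fundus photographs is a core step in
screening for diabetic retinopathy, hypertension and other vascular
conditions: vessel caliber, tortuosity and density are all read off a
pixel-level vessel map. The task is hard where it matters most — thin,
low-contrast peripheral vessels a few pixels wide.

`sfanet` implements a four-level encoder–decoder (U-shaped) convolutional
network for this task, extended with three fusion blocks, together with the
complete patch-based training and stitched whole-image inference protocol,
pixel-level evaluation (SE/SP/ACC, ROC/AUC inside the camera's field of
view), an ablation harness over the block combinations, and a procedural
synthetic fundus generator with pixel-exact labels so that the entire
pipeline is testable without any external dataset.

It is aimed at researchers who want a small, fully inspectable, CPU-only
reference implementation: the network runs on a numpy tensor engine with
reverse-mode autodiff that is part of the package (`sfanet.nn`), so every
operation from dilated convolution to the Adam update is visible and unit
tested against numerical gradients.

## The model

The backbone is a standard U-Net: four encoder levels of
`ReLU(BN(conv3x3))` pairs with 2×2 max-pooling, a bottleneck, and a
mirrored decoder. Channels double per level from a base width *w*
(defaults: *w* = 32, so 32/64/128/256 with a 512-channel bottleneck).
Three blocks refine it:

- **RASF** (residual atrous spatial feature aggregation), at the
  bottleneck. Three parallel dilated 3×3 convolutions with rates 1, 3, 5
  give multiscale maps F₁, F₂, F₃. They are fused as F₁₂ = F₁ ⊕ F₂ (sum)
  and F₂₃ = F₂ ⊗ F₃ (elementwise product); a squeeze-excitation channel
  gate computed from conv(F₁₂) re-weights F₁, a per-pixel channel softmax
  of F₂₃ re-weights F₃, and the two re-weighted maps are concatenated,
  reduced by a 3×3 convolution and added back to the input through a
  residual connection (so the block is exactly the identity at zero
  weights).
- **AFF** (attention feature fusion), on every skip connection. The
  feature entering an encoder level (pre-subsampling) is convolved and
  global-average-pooled into a channel gate that recalibrates that level's
  conv output (post-subsampling); the gated map is L2-normalized over
  channels and concatenated with the raw skip and the transpose-convolved
  decoder feature from the level below.
- **MPF** (multi-path fusion), as the head. The three finest decoder
  stages (full, 1/2 and 1/4 resolution) are bilinearly upsampled and
  convolved to a common width; the product of the two coarse paths,
  softmax-normalized over channels and pooled, gates the finest path.

A 1×1 convolution plus sigmoid produces per-pixel vessel probabilities.
Training minimizes mean binary cross entropy
−[y log p + (1−y) log(1−p)] with Adam (lr 1e-4, weight decay 1e-4,
batch 16) over randomly drawn 96×96 patches (an 80/20 train/validation
split of the patch pool — e.g. 190,000 → 152,000/38,000). Inference tiles
each image with overlapping windows and averages the stitched predictions.
Five ablation variants are constructible: `baseline`, `rasf`, `aff`,
`rasf_aff`, `full`.

## Worked example

Generate a synthetic dataset, train the full variant at reduced size, and
evaluate stitched whole-image predictions:

```sh
sfanet simulate --n 6 --size 128 --seed 7 --out data
sfanet train --manifest data/manifest.tsv --variant full --epochs 3 --seed 7 \
    --n-patches 400 --patch-size 32 --base-width 8 --out net.npz
sfanet evaluate --ckpt net.npz --manifest data/manifest.tsv --threshold 0.5 \
    --out report.json
```

which prints (abridged):

```
epoch 1: train 0.6877 val 0.6872 AUC 0.5833
epoch 2: train 0.6791 val 0.6666 AUC 0.6258
epoch 3: train 0.6704 val 0.6330 AUC 0.6674
SE 0.4247  SP 0.8719  ACC 0.8199  AUC 0.7039
```

The per-epoch lines show the training loss falling from the ln 2 ≈ 0.693
chance level and the validation pixel-AUC rising — after only ~60 optimizer
steps the network already ranks 42% of vessel pixels above threshold (SE)
at 87% specificity, with a threshold-free pixel AUC of 0.70 and climbing.
`report.json` carries the confusion counts and a per-image breakdown;
`sfanet build --variant full --summary` prints the block graph and
parameter count, and `sfanet ablate` runs all five variants and emits a
comparison table with SE/SP/ACC/AUC columns.

Loaders for the public DRIVE / CHASE_DB1 / STARE datasets (TIFF/JPEG/PPM/
GIF, plus an estimated FOV mask where none ships) use the same manifest
format, so the identical commands run on real data once downloaded;
`sfanet.training.leave_one_out_splits` provides the n-fold protocol used
for small datasets.

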