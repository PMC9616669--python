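"""Patch extraction for training and deterministic tiling for inference.

Training draws fixed-size windows uniformly at random over samples and
positions; inference tiles a whole image with a stride (edges covered by
clamped last windows) and stitches the per-patch predictions back by
per-pixel averaging, so ``reconstruct(tile(x)) == x`` for consistent
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .samples import FundusSample


@dataclass
class PatchSet:
    """Sampled patch/label pairs plus their source coordinates."""

    patches: np.ndarray          # (N, C, P, P) float
    labels: np.ndarray           # (N, 1, P, P) in {0, 1}
    coords: list                 # (sample_id, top, left) per patch
    patch_size: int

    def __post_init__(self):
        if len(self.patches) < 1:
            raise ValueError("a PatchSet needs at least one patch")
        if len(self.patches) != len(self.labels) or len(self.patches) != len(self.coords):
            raise ValueError("patches, labels and coords must align")
        if not np.isin(np.unique(self.labels), (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self):
        return len(self.patches)

    def subset(self, idx) -> "PatchSet":
        idx = np.asarray(idx)
        return PatchSet(self.patches[idx], self.labels[idx],
                        [self.coords[i] for i in idx], self.patch_size)


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must lie in (0, 1)")


def normalize_image(image_chw: np.ndarray, fov: np.ndarray) -> np.ndarray:
    """Zero-mean / unit-variance per channel over FOV pixels."""
    out = image_chw.astype(np.float64).copy()
    sel = fov.astype(bool)
    for c in range(out.shape[0]):
        vals = out[c][sel]
        sd = vals.std()
        out[c] = (out[c] - vals.mean()) / (sd if sd > 0 else 1.0)
    return out


def extract_random_patches(samples, n: int, patch_size: int, seed: int,
                           normalize: bool = True,
                           fov_only: bool = False) -> PatchSet:
    """Draw ``n`` random patch/label windows from ``samples``.

    Patch and label are cut from identical windows.  With ``fov_only`` the
    patch centre must fall inside the FOV mask.  Deterministic for a fixed
    seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    samples = list(samples)
    P = patch_size
    for s in samples:
        if s.height < P or s.width < P:
            raise ValueError(
                f"sample {s.sample_id} ({s.height}x{s.width}) smaller than patch {P}")
    rng = np.random.default_rng(seed)
    images = [normalize_image(s.image_chw(), s.fov_mask) if normalize
              else s.image_chw() for s in samples]
    c = images[0].shape[0]
    patches = np.empty((n, c, P, P), dtype=np.float64)
    labels = np.empty((n, 1, P, P), dtype=np.uint8)
    coords = []
    for i in range(n):
        while True:
            k = int(rng.integers(len(samples)))
            s = samples[k]
            top = int(rng.integers(s.height - P + 1))
            left = int(rng.integers(s.width - P + 1))
            if not fov_only:
                break
            cy, cx = top + P // 2, left + P // 2
            if s.fov_mask[cy, cx]:
                break
        patches[i] = images[k][:, top : top + P, left : left + P]
        labels[i, 0] = s.vessel_mask[top : top + P, left : left + P]
        coords.append((s.sample_id, top, left))
    return PatchSet(patches, labels, coords, P)


def split(ps: PatchSet, spec: SplitSpec):
    """Disjoint random partition into (train, validation) PatchSets.

    Sizes are round(n*f) and n - round(n*f).
    """
    n = len(ps)
    n_train = int(round(n * spec.train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError("split would leave one side empty")
    perm = np.random.default_rng(spec.seed).permutation(n)
    return ps.subset(np.sort(perm[:n_train])), ps.subset(np.sort(perm[n_train:]))


def split_indices(n: int, spec: SplitSpec):
    """Index-level counterpart of :func:`split` (same arithmetic and rng)."""
    n_train = int(round(n * spec.train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError("split would leave one side empty")
    perm = np.random.default_rng(spec.seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def tile(image: np.ndarray, patch_size: int, stride: int):
    """Deterministic tiling of a (C, H, W) or (H, W) image.

    Returns (patches (N, C, P, P), coords [(top, left)]).  Window origins
    advance by ``stride``; a clamped last window guarantees the right and
    bottom edges are covered.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    if stride > patch_size:
        raise ValueError("stride must not exceed the patch size")
    if image.ndim == 2:
        image = image[None]
    c, h, w = image.shape
    P = patch_size
    if h < P or w < P:
        raise ValueError("image smaller than patch size")

    def origins(extent):
        pos = list(range(0, extent - P + 1, stride))
        if pos[-1] != extent - P:
            pos.append(extent - P)
        return pos

    coords = [(t, l) for t in origins(h) for l in origins(w)]
    patches = np.stack([image[:, t : t + P, l : l + P] for t, l in coords])
    return patches, coords


def reconstruct(pred_patches: np.ndarray, coords, height: int, width: int) -> np.ndarray:
    """Stitch per-patch predictions into an (H, W) map by per-pixel averaging."""
    preds = np.asarray(pred_patches, dtype=np.float64)
    if preds.ndim == 4:
        preds = preds[:, 0]
    P = preds.shape[-1]
    acc = np.zeros((height, width), dtype=np.float64)
    cnt = np.zeros((height, width), dtype=np.int64)
    for p, (t, l) in zip(preds, coords):
        acc[t : t + P, l : l + P] += p
        cnt[t : t + P, l : l + P] += 1
    if (cnt == 0).any():
        raise ValueError("tiling left uncovered pixels")
    return acc / cnt
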