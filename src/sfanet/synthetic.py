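"""Procedural fundus-like images with pixel-exact vessel ground truth.

The generator emulates the gross appearance of a fundus photograph: a dark
circular field of view on a black background, a branching tree of
curvilinear vessels whose caliber tapers towards the periphery (so thin,
low-contrast vessels are always present), smooth background texture,
Gaussian blur and additive sensor noise.  The vessel label mask is the
exact rasterization of the tree before any blur or noise is applied, so
labels are pixel-perfect by construction.

Everything is deterministic given (parameters, seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .samples import FundusSample

STEP_LENGTH = 2.0          # px advanced per growth step
WIDTH_TAPER = 0.985        # per-step caliber decay along a branch
CHILD_WIDTH_RANGE = (0.6, 0.9)   # child caliber as a fraction of the parent's
MIN_WIDTH = 0.6            # growth stops below this caliber (px)
BACKGROUND_LEVEL = 0.55    # mean background intensity


@dataclass
class SynthParams:
    """Knobs of the synthetic fundus generator.

    ``contrast`` is the signed vessel-minus-background intensity difference;
    the default is negative because retinal vessels are darker than the
    surrounding tissue.  ``tortuosity`` is the standard deviation (radians)
    of the random heading change per growth step.
    """

    size: int = 128
    n_roots: int = 4
    branch_prob: float = 0.08
    width_range: tuple = (1.0, 2.5)
    tortuosity: float = 0.18
    contrast: float = -0.35
    noise_std: float = 0.03
    blur_sigma: float = 0.8
    fov_radius_frac: float = 0.48
    texture_amp: float = 0.05
    max_depth: int = 4
    max_steps: int = 120
    channels: int = 1

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("image size must be at least 32 px")
        lo, hi = self.width_range
        if not (0 < lo <= hi):
            raise ValueError("width range must satisfy 0 < min <= max")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch probability must lie in [0, 1]")
        if not -1.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [-1, 1]")
        if self.noise_std < 0 or self.blur_sigma < 0 or self.texture_amp < 0:
            raise ValueError("noise, blur and texture amplitudes must be >= 0")
        if not 0.0 < self.fov_radius_frac <= 0.5:
            raise ValueError("fov radius fraction must lie in (0, 0.5]")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        self.width_range = tuple(self.width_range)


@dataclass
class Segment:
    """One straight piece of a vessel branch, in (x, y) image coordinates.

    ``parent`` is the index of the preceding segment in the tree (-1 for the
    first segment of a root), enabling exhaustive parent/child walks.
    """

    start: tuple
    end: tuple
    width: float
    depth: int
    parent: int = -1


@dataclass
class VesselTree:
    segments: list
    roots: list
    size: int

    def __post_init__(self):
        for s in self.segments:
            if s.width <= 0:
                raise ValueError("segment widths must be strictly positive")
            coords = (*s.start, *s.end)
            if not np.isfinite(coords).all():
                raise ValueError("segment coordinates must be finite")


def _inside_fov(p, centre, radius, margin):
    return np.hypot(p[0] - centre, p[1] - centre) <= radius - margin


def generate_vessel_tree(params: SynthParams, seed: int) -> VesselTree:
    """Grow a branching vessel tree inside the FOV disk.

    Each root starts near the FOV rim heading inward and advances in fixed
    steps with a random heading perturbation; side branches spawn with
    probability ``branch_prob`` per step, with caliber reduced by a factor
    drawn from ``CHILD_WIDTH_RANGE`` so that a child is never wider than its
    parent.  Growth stops when the caliber falls below ``MIN_WIDTH``, the
    branch would leave the FOV, or ``max_steps`` is exhausted.
    """
    rng = np.random.default_rng(seed)
    centre = params.size / 2.0
    radius = params.fov_radius_frac * params.size
    segments: list[Segment] = []
    roots: list[tuple] = []

    lo_w, hi_w = params.width_range
    for _ in range(params.n_roots):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        start = (centre + 0.85 * radius * np.cos(phi),
                 centre + 0.85 * radius * np.sin(phi))
        heading = phi + np.pi + rng.normal(0.0, 0.3)   # point roughly inward
        width = rng.uniform(lo_w, hi_w)
        roots.append(start)
        # stack of branch tips: (position, heading, width, depth, steps left,
        # index of the parent segment)
        tips = [(start, heading, width, 0, params.max_steps, -1)]
        while tips:
            pos, ang, w, depth, budget, parent = tips.pop()
            while budget > 0 and w >= MIN_WIDTH:
                ang += rng.normal(0.0, params.tortuosity)
                nxt = (pos[0] + STEP_LENGTH * np.cos(ang),
                       pos[1] + STEP_LENGTH * np.sin(ang))
                if not _inside_fov(nxt, centre, radius, margin=w / 2 + 1.0):
                    break
                segments.append(Segment(pos, nxt, w, depth, parent))
                parent = len(segments) - 1
                pos = nxt
                w *= WIDTH_TAPER
                budget -= 1
                if (depth < params.max_depth and w > MIN_WIDTH
                        and rng.random() < params.branch_prob):
                    side = rng.choice((-1.0, 1.0)) * rng.uniform(0.5, 1.1)
                    child_w = w * rng.uniform(*CHILD_WIDTH_RANGE)
                    tips.append((pos, ang + side, child_w, depth + 1, budget, parent))
    return VesselTree(segments=segments, roots=roots, size=params.size)


def rasterize_tree(tree: VesselTree, size: int) -> np.ndarray:
    """Exact binary rasterization: a pixel is vessel iff its centre lies
    within ``width/2`` of some segment (the continuum limit of stamping
    disks at sub-pixel steps along each segment)."""
    mask = np.zeros((size, size), dtype=np.uint8)
    for seg in tree.segments:
        r = seg.width / 2.0
        x0, y0 = seg.start
        x1, y1 = seg.end
        lo_x = max(int(np.floor(min(x0, x1) - r - 1)), 0)
        hi_x = min(int(np.ceil(max(x0, x1) + r + 1)), size - 1)
        lo_y = max(int(np.floor(min(y0, y1) - r - 1)), 0)
        hi_y = min(int(np.ceil(max(y0, y1) + r + 1)), size - 1)
        if lo_x > hi_x or lo_y > hi_y:
            continue
        ys, xs = np.mgrid[lo_y : hi_y + 1, lo_x : hi_x + 1]
        dx, dy = x1 - x0, y1 - y0
        seg_len2 = dx * dx + dy * dy
        if seg_len2 == 0:
            t = np.zeros_like(xs, dtype=float)
        else:
            t = np.clip(((xs - x0) * dx + (ys - y0) * dy) / seg_len2, 0.0, 1.0)
        dist = np.hypot(xs - (x0 + t * dx), ys - (y0 + t * dy))
        mask[lo_y : hi_y + 1, lo_x : hi_x + 1] |= (dist <= r).astype(np.uint8)
    return mask


def fov_disk(size: int, radius_frac: float) -> np.ndarray:
    centre = size / 2.0
    ys, xs = np.mgrid[0:size, 0:size]
    dist = np.hypot(xs + 0.5 - centre, ys + 0.5 - centre)
    return (dist <= radius_frac * size).astype(np.uint8)


def render_sample(tree: VesselTree, params: SynthParams, seed: int,
                  sample_id: str = "synth") -> FundusSample:
    """Render a tree into an image + masks.

    The label mask is the exact pre-blur, pre-noise rasterization.  The image
    starts from a smoothly textured background at ``BACKGROUND_LEVEL``;
    vessel pixels are painted at exactly ``BACKGROUND_LEVEL + contrast``,
    then Gaussian blur and white noise are applied, the result is clipped to
    [0, 1] and zeroed outside the FOV disk.
    """
    if tree.size != params.size:
        raise ValueError("tree was generated for a different image size")
    rng = np.random.default_rng(seed)
    size = params.size
    vessel = rasterize_tree(tree, size)
    fov = fov_disk(size, params.fov_radius_frac)
    vessel &= fov

    image = np.full((size, size), BACKGROUND_LEVEL, dtype=np.float64)
    if params.texture_amp > 0:
        texture = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), size / 16.0)
        sd = texture.std()
        if sd > 0:
            image += params.texture_amp * texture / sd
    image[vessel == 1] = BACKGROUND_LEVEL + params.contrast
    if params.blur_sigma > 0:
        image = gaussian_filter(image, params.blur_sigma)
    if params.noise_std > 0:
        image = image + rng.normal(0.0, params.noise_std, image.shape)
    image = np.clip(image, 0.0, 1.0) * fov
    if params.channels == 3:
        image = np.repeat(image[:, :, None], 3, axis=2)
    return FundusSample(image=image, vessel_mask=vessel, fov_mask=fov,
                        sample_id=sample_id, source="synthetic",
                        meta={"seed": seed})


def generate_sample(params: SynthParams, seed: int, sample_id: str = "synth") -> FundusSample:
    """Convenience: grow a tree and render it with sub-seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed).spawn(2)
    tree = generate_vessel_tree(params, seed=ss[0].generate_state(1)[0] % (2**31))
    return render_sample(tree, params, seed=ss[1].generate_state(1)[0] % (2**31),
                         sample_id=sample_id)


def generate_dataset(n: int, params: SynthParams, seed: int,
                     out_dir: str | Path | None = None,
                     force: bool = False) -> list[FundusSample]:
    """Generate ``n`` samples with per-sample sub-seeds derived from ``seed``.

    With ``out_dir`` set, writes image/mask PNGs and a tab-separated manifest
    (columns: sample_id, image, gt, fov, source, seed); refuses to overwrite
    an existing manifest unless ``force``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n)
    samples = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        samples.append(generate_sample(params, sub_seed, sample_id=f"synth_{i:04d}"))

    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        manifest = out / "manifest.tsv"
        if manifest.exists() and not force:
            raise FileExistsError(f"{manifest} exists; pass force=True to overwrite")
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for s in samples:
            img_path = out / f"{s.sample_id}.png"
            gt_path = out / f"{s.sample_id}_gt.png"
            fov_path = out / f"{s.sample_id}_fov.png"
            if s.image.ndim == 2:       # 16-bit grayscale keeps full precision
                iio.imwrite(img_path, np.round(s.image * 65535).astype(np.uint16))
            else:
                iio.imwrite(img_path, np.round(s.image * 255).astype(np.uint8))
            iio.imwrite(gt_path, (s.vessel_mask * 255).astype(np.uint8))
            iio.imwrite(fov_path, (s.fov_mask * 255).astype(np.uint8))
            rows.append({"sample_id": s.sample_id, "image": img_path.name,
                         "gt": gt_path.name, "fov": fov_path.name,
                         "source": "synthetic", "seed": s.meta["seed"]})
        with open(manifest, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
            writer.writeheader()
            writer.writerows(rows)
    return samples
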