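"""Dataset ingestion (public fundus formats and the synthetic format),
manifests and run configuration.

Images are read with imageio (TIFF, JPEG, PPM, PNG, GIF — the formats the
public retinal datasets ship in), scaled to [0, 1]; ground-truth masks are
binarized at mid-gray.  A missing FOV mask is replaced by an all-ones mask
with a logged warning; for images with a dark surround (e.g. STARE, which
has no official FOV masks) an intensity-based FOV estimate is provided.

Array convention throughout: row-major, origin top-left, (H, W) ordering.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .samples import SOURCES, FundusSample

log = logging.getLogger(__name__)


def _to_unit(arr: np.ndarray) -> np.ndarray:
    """Scale an integer or float image to float64 in [0, 1]."""
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr = arr / arr.max()
    return np.clip(arr, 0.0, 1.0)


def _binarize(arr: np.ndarray) -> np.ndarray:
    """Binarize a mask image at mid-gray."""
    return (_to_unit(arr) >= 0.5).astype(np.uint8)


def read_image(path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:    # drop alpha
        arr = arr[:, :, :3]
    return arr


def load_sample(row: dict, root: str | Path = ".") -> FundusSample:
    """Load one manifest row into a FundusSample.

    ``row`` needs keys sample_id, image, gt and optionally fov and source.
    The image is scaled to [0, 1]; the ground truth is binarized at
    mid-gray; a missing FOV yields an all-ones mask and a warning.
    """
    root = Path(root)
    image = _to_unit(read_image(root / row["image"]))
    if image.ndim == 3 and image.shape[2] == 1:
        image = image[:, :, 0]
    gt_raw = read_image(root / row["gt"])
    if gt_raw.ndim == 3:
        gt_raw = gt_raw[:, :, 0]
    gt = _binarize(gt_raw)
    if gt.shape != image.shape[:2]:
        raise ValueError(
            f"{row['sample_id']}: ground truth {gt.shape} does not match "
            f"image {image.shape[:2]}")
    fov_path = row.get("fov") or ""
    if fov_path and fov_path.lower() not in ("none", "-"):
        fov_raw = read_image(root / fov_path)
        if fov_raw.ndim == 3:
            fov_raw = fov_raw[:, :, 0]
        fov = _binarize(fov_raw)
    else:
        log.warning("%s: no FOV mask; using the full frame", row["sample_id"])
        fov = np.ones(image.shape[:2], dtype=np.uint8)
    gt &= fov   # a vessel label outside the FOV is unusable by definition
    source = row.get("source", "user")
    if source not in SOURCES:
        source = "user"
    return FundusSample(image=image, vessel_mask=gt, fov_mask=fov,
                        sample_id=row["sample_id"], source=source)


def estimate_fov(image: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Derive an FOV mask by thresholding intensity against the dark border.

    Intended for datasets without official FOV masks; flagged as an
    estimate, not ground truth.
    """
    from scipy.ndimage import binary_closing, binary_fill_holes, label

    gray = image if image.ndim == 2 else _to_unit(image).mean(axis=2)
    mask = gray > threshold
    mask = binary_closing(mask, iterations=2)
    mask = binary_fill_holes(mask)
    lab, n = label(mask)
    if n > 1:   # keep the largest connected component
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask.astype(np.uint8)


# -- manifests ----------------------------------------------------------------

MANIFEST_FIELDS = ("sample_id", "image", "gt", "fov", "source")


def load_manifest(path) -> list[dict]:
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"empty manifest: {path}")
    ids = [r["sample_id"] for r in rows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids in manifest")
    return rows


def load_samples(manifest_path) -> list[FundusSample]:
    path = Path(manifest_path)
    return [load_sample(row, root=path.parent) for row in load_manifest(path)]


# -- run configuration --------------------------------------------------------


@dataclass
class EvalConfig:
    threshold: float = 0.5
    stride: int | None = None
    fov_restricted: bool = True
    normalize: bool = True


@dataclass
class RunConfig:
    """Nested configuration for a full run; YAML round-trippable."""

    network: "NetworkConfig" = None          # type: ignore[assignment]
    train: "TrainConfig" = None              # type: ignore[assignment]
    synth: "SynthParams" = None              # type: ignore[assignment]
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self):
        from .network import NetworkConfig
        from .synthetic import SynthParams
        from .training import TrainConfig

        if self.network is None:
            self.network = NetworkConfig()
        if self.train is None:
            self.train = TrainConfig()
        if self.synth is None:
            self.synth = SynthParams()

    def to_dict(self) -> dict:
        return {
            "network": self.network.to_dict(),
            "train": dict(vars(self.train)),
            "synth": dict(vars(self.synth), width_range=list(self.synth.width_range)),
            "evaluation": dict(vars(self.evaluation)),
        }


def save_config(cfg: RunConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    from .network import NetworkConfig
    from .synthetic import SynthParams
    from .training import TrainConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"network", "train", "synth", "evaluation"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    sections = {}
    for name, cls in (("network", NetworkConfig), ("train", TrainConfig),
                      ("synth", SynthParams), ("evaluation", EvalConfig)):
        entries = raw.get(name, {})
        valid = set(cls.__dataclass_fields__)
        bad = set(entries) - valid
        if bad:
            raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
        sections[name] = cls(**entries)
    return RunConfig(network=sections["network"], train=sections["train"],
                     synth=sections["synth"], evaluation=sections["evaluation"])
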