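"""Dataset containers shared by the synthetic generator, loaders and metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SOURCES = ("synthetic", "drive", "chase", "stare", "user")


@dataclass
class FundusSample:
    """One fundus image with its vessel ground truth and field-of-view mask.

    ``image`` is float in [0, 1], either (H, W) grayscale or (H, W, 3) RGB;
    ``vessel_mask`` and ``fov_mask`` are binary (H, W) arrays with values in
    {0, 1}, and every vessel pixel lies inside the FOV.
    """

    image: np.ndarray
    vessel_mask: np.ndarray
    fov_mask: np.ndarray
    sample_id: str
    source: str = "user"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.vessel_mask = np.asarray(self.vessel_mask)
        self.fov_mask = np.asarray(self.fov_mask)
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")
        hw = self.image.shape[:2]
        if self.vessel_mask.shape != hw or self.fov_mask.shape != hw:
            raise ValueError("image and masks must share height and width")
        for name, m in (("vessel_mask", self.vessel_mask), ("fov_mask", self.fov_mask)):
            vals = np.unique(m)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"{name} must be exactly binary, got values {vals}")
        self.vessel_mask = self.vessel_mask.astype(np.uint8)
        self.fov_mask = self.fov_mask.astype(np.uint8)
        if np.any(self.vessel_mask & ~self.fov_mask):
            raise ValueError("vessel pixels must lie inside the FOV mask")
        if not np.isfinite(self.image).all():
            raise ValueError("image contains non-finite values")

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.image.ndim == 2 else self.image.shape[2]

    def image_chw(self) -> np.ndarray:
        """Image as a (C, H, W) float array."""
        if self.image.ndim == 2:
            return self.image[None]
        return np.ascontiguousarray(self.image.transpose(2, 0, 1))
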