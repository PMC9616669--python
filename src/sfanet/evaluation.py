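"""Pixel-level segmentation scoring restricted to field-of-view pixels.

Confusion counts at a threshold give sensitivity SE = TP/(TP+FN),
specificity SP = TN/(FP+TN) and accuracy ACC = (TP+TN)/(TP+TN+FP+FN); the
threshold-free summary is the ROC curve over all distinct score values and
its trapezoidal area (AUC), which equals the Mann-Whitney probability that
a random vessel pixel outscores a random background pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero (e.g. no positive pixels in the FOV)."""


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class MetricsReport:
    se: float
    sp: float
    acc: float
    auc: float
    threshold: float
    counts: ConfusionCounts
    per_sample: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "se": self.se, "sp": self.sp, "acc": self.acc, "auc": self.auc,
            "threshold": self.threshold,
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "tn": self.counts.tn, "fn": self.counts.fn},
            "per_sample": self.per_sample,
        }


def _check_binary(mask: np.ndarray, name: str):
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary, got values {vals}")


def confusion(prob: np.ndarray, gt: np.ndarray, fov: np.ndarray,
              threshold: float = 0.5) -> ConfusionCounts:
    """Binarize ``prob >= threshold`` and count against ``gt`` over FOV pixels."""
    prob, gt, fov = (np.asarray(a) for a in (prob, gt, fov))
    if not (prob.shape == gt.shape == fov.shape):
        raise ValueError("prob, gt and fov must share shape")
    _check_binary(gt, "gt")
    _check_binary(fov, "fov")
    sel = fov.astype(bool)
    pred = prob[sel] >= threshold
    truth = gt[sel].astype(bool)
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return ConfusionCounts(tp, fp, tn, fn)


def se_sp_acc(c: ConfusionCounts) -> tuple[float, float, float]:
    """Sensitivity, specificity and accuracy from confusion counts."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive pixels")
    if c.fp + c.tn == 0:
        raise UndefinedMetricError("specificity undefined: no negative pixels")
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: no evaluated pixels")
    se = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.fp + c.tn)
    acc = (c.tp + c.tn) / c.total
    return se, sp, acc


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[ROCCurve, float]:
    """ROC sweep over distinct score values and trapezoidal AUC.

    ``labels`` must contain at least one positive and one negative.  Equal
    scores collapse to one operating point, which makes the trapezoidal area
    equal to the tie-aware Mann-Whitney statistic.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative pixel")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp_cum = np.cumsum(y)
    fp_cum = np.cumsum(~y)
    distinct = np.nonzero(np.diff(s))[0]           # last index of each tie block
    idx = np.concatenate([distinct, [s.size - 1]])
    tpr = np.concatenate([[0.0], tp_cum[idx] / n_pos])
    fpr = np.concatenate([[0.0], fp_cum[idx] / n_neg])
    thresholds = np.concatenate([[np.inf], s[idx]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds), auc


def predict_image(net, image_chw: np.ndarray, patch_size: int | None = None,
                  stride: int | None = None, batch_size: int = 16) -> np.ndarray:
    """Tile -> forward (eval mode) -> stitch one image into an (H, W) map."""
    from .patches import reconstruct, tile

    P = patch_size or net.config.patch_size
    stride = stride or max(P // 2, 1)
    if image_chw.ndim == 2:
        image_chw = image_chw[None]
    _, h, w = image_chw.shape
    tiles, coords = tile(image_chw, P, stride)
    preds = np.concatenate([net.predict(tiles[i : i + batch_size])
                            for i in range(0, len(tiles), batch_size)])
    return reconstruct(preds, coords, h, w)


def evaluate(net, samples, threshold: float = 0.5, stride: int | None = None,
             normalize: bool = True, fov_restricted: bool = True,
             batch_size: int = 16) -> MetricsReport:
    """Whole-image evaluation: stitched prediction per sample, pixels pooled.

    Metrics are micro-averaged over all evaluated pixels (those inside the
    FOV unless ``fov_restricted`` is off); a per-sample breakdown is
    attached.
    """
    from .patches import normalize_image

    pooled_scores, pooled_labels = [], []
    total = ConfusionCounts(0, 0, 0, 0)
    per_sample = []
    for s in samples:
        img = s.image_chw()
        if normalize:
            img = normalize_image(img, s.fov_mask)
        prob = predict_image(net, img, stride=stride, batch_size=batch_size)
        fov = s.fov_mask if fov_restricted else np.ones_like(s.fov_mask)
        c = confusion(prob, s.vessel_mask, fov, threshold)
        total = total + c
        sel = fov.astype(bool)
        pooled_scores.append(prob[sel])
        pooled_labels.append(s.vessel_mask[sel])
        entry = {"sample_id": s.sample_id,
                 "counts": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}}
        try:
            entry["se"], entry["sp"], entry["acc"] = se_sp_acc(c)
            _, entry["auc"] = roc_auc(prob[sel], s.vessel_mask[sel])
        except (UndefinedMetricError, ValueError):
            pass
        per_sample.append(entry)
    se, sp, acc = se_sp_acc(total)
    _, auc = roc_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return MetricsReport(se=se, sp=sp, acc=acc, auc=auc, threshold=threshold,
                         counts=total, per_sample=per_sample)
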