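"""Segmentation metrics from pixel confusion counts, throughput, overlays.

All metrics derive from one (k+1) x (k+1) confusion matrix (rows = true
class, columns = predicted class; k+1 = 3 classes here):

    MIoU      = mean_c  TP_c / (TP_c + FP_c + FN_c)
    recall_c  = TP_c / (TP_c + FN_c)
    precision_c = TP_c / (TP_c + FP_c)

Precision/recall are macro-averaged over classes by default (matching the
class mean in MIoU); ``mode="foreground"`` restricts the mean to the corn
and weed classes. Classes absent from both truth and prediction (zero
denominator) are excluded from averages rather than scored zero, so images
lacking a class are not penalized.
"""

from __future__ import annotations

import platform
import time
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import ShapeError, SpecificationError, UndefinedMetricError
from .scene import N_CLASSES, LabeledScene


class ConfusionMatrix:
    """Pixel-count confusion table; accumulation is associative, so batches
    may be added in any order."""

    def __init__(self, n_classes: int = N_CLASSES,
                 counts: Optional[np.ndarray] = None):
        self.n_classes = n_classes
        self.counts = (np.zeros((n_classes, n_classes), np.int64)
                       if counts is None else np.asarray(counts, np.int64))
        if self.counts.shape != (n_classes, n_classes):
            raise ShapeError("confusion counts must be (k+1) x (k+1)")

    # per-class decompositions
    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.counts.sum() - self.tp - self.fp - self.fn

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.n_classes, self.counts + other.counts)


def accumulate_confusion(pred: np.ndarray, truth: np.ndarray,
                         cm: Optional[ConfusionMatrix] = None
                         ) -> ConfusionMatrix:
    """Add one prediction/truth pair (any matching shape) into ``cm``."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeError(
            f"prediction shape {pred.shape} != truth shape {truth.shape}")
    if cm is None:
        cm = ConfusionMatrix()
    k = cm.n_classes
    if pred.max(initial=0) >= k or truth.max(initial=0) >= k:
        raise ShapeError(f"class index out of range for {k} classes")
    flat = truth.astype(np.int64).ravel() * k + pred.astype(np.int64).ravel()
    cm.counts += np.bincount(flat, minlength=k * k).reshape(k, k)
    return cm


def per_class_iou(cm: ConfusionMatrix) -> np.ndarray:
    """IoU per class; NaN where the class is absent from truth and pred."""
    denom = cm.tp + cm.fp + cm.fn
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, cm.tp / denom, np.nan)


def miou(cm: ConfusionMatrix) -> float:
    """Mean IoU over classes with a nonzero denominator."""
    ious = per_class_iou(cm)
    valid = ~np.isnan(ious)
    if not valid.any():
        raise UndefinedMetricError("no class present in truth or prediction")
    return float(ious[valid].mean())


def per_class_precision_recall(cm: ConfusionMatrix
                               ) -> Tuple[np.ndarray, np.ndarray]:
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(cm.tp + cm.fp > 0, cm.tp / (cm.tp + cm.fp), np.nan)
        rec = np.where(cm.tp + cm.fn > 0, cm.tp / (cm.tp + cm.fn), np.nan)
    return prec, rec


def precision_recall(cm: ConfusionMatrix, mode: str = "macro"
                     ) -> Tuple[float, float]:
    """Averaged (precision, recall); ``mode`` is 'macro' (all classes) or
    'foreground' (corn + weed only)."""
    prec, rec = per_class_precision_recall(cm)
    if mode == "foreground":
        prec, rec = prec[1:], rec[1:]
    elif mode != "macro":
        raise SpecificationError(f"unknown averaging mode {mode!r}")
    vp, vr = ~np.isnan(prec), ~np.isnan(rec)
    if not vp.any() or not vr.any():
        raise UndefinedMetricError("no valid class for precision/recall")
    return float(prec[vp].mean()), float(rec[vr].mean())


# ---------------------------------------------------------------------------
# throughput (informational; hardware-dependent by nature)
# ---------------------------------------------------------------------------

def measure_fps(model, image_size: int = 224, n_frames: int = 10,
                warmup: int = 2) -> Dict[str, object]:
    """Mean single-image forward throughput after warm-up.

    Reported with a hardware descriptor; never comparable across machines.
    """
    from . import network

    if n_frames < 1:
        raise SpecificationError(f"n_frames must be >= 1, got {n_frames}")
    rng = np.random.default_rng(0)
    img = rng.standard_normal((1, 3, image_size, image_size)).astype(np.float32)
    for _ in range(warmup):
        network.forward(model, img)
    t0 = time.perf_counter()
    for _ in range(n_frames):
        network.forward(model, img)
    dt = (time.perf_counter() - t0) / n_frames
    return {"fps": 1.0 / dt, "seconds_per_frame": dt,
            "hardware": f"{platform.machine()} / {platform.processor() or 'cpu'}"}


# ---------------------------------------------------------------------------
# qualitative rendering
# ---------------------------------------------------------------------------

_OVERLAY_COLORS = {1: np.array([0, 255, 0], float),     # corn: green
                   2: np.array([255, 0, 0], float)}     # weed: red


def render_overlay(image: np.ndarray, mask: np.ndarray,
                   alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend class colors over the image; background untouched."""
    if mask.shape != image.shape[:2]:
        raise ShapeError("mask/image shape mismatch")
    out = image.astype(np.float64).copy()
    for cls, color in _OVERLAY_COLORS.items():
        sel = mask == cls
        out[sel] = (1 - alpha) * out[sel] + alpha * color
    return np.round(out).clip(0, 255).astype(np.uint8)


def make_panel(image: np.ndarray, truth: np.ndarray, pred: np.ndarray,
               sep: int = 2, alpha: float = 0.5) -> np.ndarray:
    """Side-by-side (image | truth overlay | prediction overlay) panel of
    width 3W + 2*sep."""
    panels = [image, render_overlay(image, truth, alpha),
              render_overlay(image, pred, alpha)]
    h, w = image.shape[:2]
    strip = np.full((h, sep, 3), 255, np.uint8)
    parts = []
    for i, p in enumerate(panels):
        parts.append(p)
        if i < 2:
            parts.append(strip)
    return np.concatenate(parts, axis=1)


# ---------------------------------------------------------------------------
# dataset-level evaluation and reporting
# ---------------------------------------------------------------------------

def evaluate_masks(preds, truths) -> Dict[str, float]:
    cm = ConfusionMatrix()
    for p, t in zip(preds, truths):
        accumulate_confusion(p, t, cm)
    p, r = precision_recall(cm)
    return {"miou": miou(cm), "precision": p, "recall": r,
            "pixels": cm.total}


def write_metrics_report(path, metrics: Dict[str, object]) -> None:
    """Tab-delimited key/value report mirroring the MIoU%/Precision%/Recall%
    column convention (fractions are also given as percentages)."""
    lines = []
    for key, val in metrics.items():
        lines.append(f"{key}\t{val}")
        if key in ("miou", "precision", "recall") and isinstance(val, float):
            lines.append(f"{key}_percent\t{100.0 * val:.2f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
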