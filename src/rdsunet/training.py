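"""Training protocol: random init, multiclass soft Dice loss, Adam.

Defaults follow the reference protocol exactly: 100 epochs, batch size 4,
learning rate 0.001, Adam with beta1 = 0.9 (the stated "momentum 0.9" read
as Adam's first-moment coefficient, since Adam has no classical momentum),
weight decay 1e-4 (the stated "decay rate").

The Dice loss softmaxes the logits and computes a per-class soft Dice
coefficient over the whole batch,

    d_k = (2 sum p_k t_k + eps) / (sum p_k + sum t_k + eps),  eps = 1e-6,

with one-hot truth t; the loss is 1 - mean_k d_k over all classes
(background included by default; configurable).

Images are scaled to [0, 1] and standardized per channel with statistics
computed on the training split; the statistics are frozen into every
checkpoint so evaluation always normalizes identically.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import nn
from .errors import (DivergenceError, FormatError, SpecificationError)
from .evaluation import (ConfusionMatrix, accumulate_confusion, miou,
                         precision_recall)
from .network import ModelVariant, SegmentationModel, build_model
from .vocdata import DatasetIndex, load_sample

DICE_EPS = 1e-6


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 4
    learning_rate: float = 1e-3
    beta1: float = 0.9
    weight_decay: float = 1e-4
    loss: str = "dice"
    include_background: bool = True
    seed: int = 0
    device: str = "cpu"
    checkpoint_dir: Optional[str] = None
    image_size: Optional[int] = None          # None = stored resolution
    max_steps: Optional[int] = None           # optional step cap per run
    stop_at_train_miou: Optional[float] = None  # optional early target

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise SpecificationError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0 or not 0 <= self.beta1 < 1:
            raise SpecificationError("invalid learning_rate/beta1")
        if self.weight_decay < 0:
            raise SpecificationError("weight_decay must be >= 0")
        if self.loss != "dice":
            raise SpecificationError(f"unsupported loss {self.loss!r}")
        if self.device not in ("cpu", "accelerator"):
            raise SpecificationError(f"unknown device {self.device!r}")


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def dice_loss(logits, truth: np.ndarray,
              include_background: bool = True) -> nn.Tensor:
    """Soft Dice loss of (B, K, H, W) logits against (B, H, W) class indices.

    Always in [0, 1]; 0 iff the softmax puts all mass on the true class.
    """
    if not isinstance(logits, nn.Tensor):
        logits = nn.Tensor(logits)
    b, k, h, w = logits.shape
    truth = np.asarray(truth)
    if truth.shape != (b, h, w):
        raise FormatError(
            f"truth shape {truth.shape} does not match logits {(b, h, w)}")
    if truth.min(initial=0) < 0 or truth.max(initial=0) >= k:
        raise FormatError(
            f"truth contains class index outside 0..{k - 1}")
    onehot = np.zeros((b, k, h, w), np.float32)
    np.put_along_axis(onehot, truth[:, None].astype(np.int64), 1.0, axis=1)
    probs = logits.log_softmax(axis=1).exp()
    inter = (probs * onehot).sum(axis=(0, 2, 3))          # (K,)
    denom = probs.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3))
    dice = (inter * 2.0 + DICE_EPS) / (denom + DICE_EPS)
    if not include_background:
        dice = dice[1:]
    return 1.0 - dice.mean()


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class Normalizer:
    """Per-channel standardization fitted on the training split."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, images: np.ndarray) -> "Normalizer":
        x = images.astype(np.float32) / 255.0
        return cls(mean=x.mean(axis=(0, 1, 2)),
                   std=np.maximum(x.std(axis=(0, 1, 2)), 1e-4))

    def apply(self, images: np.ndarray) -> np.ndarray:
        """(n, H, W, 3) uint8 -> (n, 3, H, W) float32 standardized."""
        x = images.astype(np.float32) / 255.0
        x = (x - self.mean) / self.std
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


# ---------------------------------------------------------------------------
# history
# ---------------------------------------------------------------------------

@dataclass
class TrainHistory:
    records: List[Dict[str, float]] = field(default_factory=list)
    step_losses: List[float] = field(default_factory=list)

    def append(self, **kw) -> None:
        self.records.append({k: float(v) for k, v in kw.items()})

    def __len__(self):
        return len(self.records)

    def to_csv(self, path) -> None:
        if not self.records:
            Path(path).write_text("")
            return
        cols = list(self.records[0])
        lines = ["\t".join(cols)]
        for r in self.records:
            lines.append("\t".join(f"{r[c]:.6g}" for c in cols))
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: SegmentationModel,
                    normalizer: Optional[Normalizer] = None,
                    config: Optional[TrainConfig] = None,
                    epoch: int = 0, optimizer=None) -> None:
    arrays = {f"model/{k}": v for k, v in model.state_dict().items()}
    if optimizer is not None:
        arrays.update({f"opt/{k}": v
                       for k, v in optimizer.state_dict().items()})
    if normalizer is not None:
        arrays["norm/mean"] = normalizer.mean
        arrays["norm/std"] = normalizer.std
    meta = {"variant": asdict(model.variant), "epoch": epoch,
            "config": asdict(config) if config else None}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Return (model, normalizer, meta dict, raw arrays)."""
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(bytes(arrays.pop("meta")).decode())
    variant = ModelVariant(**meta["variant"])
    model = build_model(variant)
    model.load_state_dict({k[len("model/"):]: v for k, v in arrays.items()
                           if k.startswith("model/")})
    norm = None
    if "norm/mean" in arrays:
        norm = Normalizer(mean=arrays["norm/mean"], std=arrays["norm/std"])
    return model, norm, meta, arrays


# ---------------------------------------------------------------------------
# core loop (array interface)
# ---------------------------------------------------------------------------

def _eval_arrays(model, x: np.ndarray, y: np.ndarray, batch_size: int,
                 include_background: bool) -> Dict[str, float]:
    model.eval()
    cm = ConfusionMatrix()
    total_loss, n_batches = 0.0, 0
    with nn.no_grad():
        for i in range(0, len(x), batch_size):
            xb, yb = x[i:i + batch_size], y[i:i + batch_size]
            logits = model(nn.Tensor(xb))
            total_loss += dice_loss(logits, yb, include_background).item()
            n_batches += 1
            accumulate_confusion(logits.data.argmax(axis=1), yb, cm)
    model.train()
    p, r = precision_recall(cm)
    return {"loss": total_loss / max(n_batches, 1), "miou": miou(cm),
            "precision": p, "recall": r}


def fit_arrays(model: SegmentationModel,
               x_train: np.ndarray, y_train: np.ndarray,
               config: TrainConfig,
               x_val: Optional[np.ndarray] = None,
               y_val: Optional[np.ndarray] = None,
               history: Optional[TrainHistory] = None,
               optimizer: Optional[nn.Adam] = None,
               start_epoch: int = 0,
               on_epoch_end=None) -> Tuple[TrainHistory, nn.Adam]:
    """Seeded mini-batch training on pre-normalized arrays.

    x_*: (n, 3, H, W) float32; y_*: (n, H, W) int. Stops early when
    ``max_steps`` or ``stop_at_train_miou`` (training-split MIoU) is hit.
    """
    if len(x_train) == 0:
        raise SpecificationError("training split is empty")
    history = history if history is not None else TrainHistory()
    optimizer = optimizer if optimizer is not None else nn.Adam(
        model.parameters(), lr=config.learning_rate, beta1=config.beta1,
        weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    # keep the shuffle stream aligned when resuming mid-run
    for _ in range(start_epoch):
        rng.permutation(len(x_train))
    step = len(history.step_losses)
    model.train()
    for epoch in range(start_epoch, config.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(len(x_train))
        cm = ConfusionMatrix()
        epoch_loss, n_batches = 0.0, 0
        stop = False
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            xb = nn.Tensor(x_train[sel])
            yb = y_train[sel]
            logits = model(xb)
            loss = dice_loss(logits, yb, config.include_background)
            lv = loss.item()
            if not np.isfinite(lv):
                raise DivergenceError(epoch + 1, step + 1, lv)
            model.zero_grad()
            loss.backward()
            optimizer.step()
            history.step_losses.append(lv)
            epoch_loss += lv
            n_batches += 1
            step += 1
            accumulate_confusion(logits.data.argmax(axis=1), yb, cm)
            if config.max_steps is not None and step >= config.max_steps:
                stop = True
                break
            if (config.stop_at_train_miou is not None
                    and miou(cm) > config.stop_at_train_miou):
                stop = True
                break
        rec = {"epoch": epoch + 1,
               "train_loss": epoch_loss / max(n_batches, 1),
               "train_miou": miou(cm),
               "seconds": time.perf_counter() - t0}
        if x_val is not None and len(x_val):
            val = _eval_arrays(model, x_val, y_val, config.batch_size,
                               config.include_background)
            rec.update(val_loss=val["loss"], val_miou=val["miou"],
                       val_precision=val["precision"],
                       val_recall=val["recall"])
        history.append(**rec)
        if on_epoch_end is not None:
            on_epoch_end(epoch + 1, rec)
        if stop:
            break
    return history, optimizer


# ---------------------------------------------------------------------------
# dataset interface
# ---------------------------------------------------------------------------

def _load_split_arrays(data: DatasetIndex, split: str,
                       image_size: Optional[int]
                       ) -> Tuple[np.ndarray, np.ndarray]:
    ids = data.split_ids(split)
    imgs, masks = [], []
    for sid in ids:
        s = load_sample(data, sid, target_size=image_size)
        imgs.append(s.image)
        masks.append(s.mask)
    if not imgs:
        return np.empty((0,)), np.empty((0,))
    return np.stack(imgs), np.stack(masks).astype(np.int64)


def train(model: SegmentationModel, data: DatasetIndex,
          config: TrainConfig, resume: Optional[str] = None
          ) -> Tuple[TrainHistory, Dict[str, str]]:
    """Full training run over a VOC dataset's train/val splits.

    Retains both the last checkpoint and the best-validation-MIoU
    checkpoint; the run is resumable from the last checkpoint and fully
    reproducible from (config, seed).
    """
    imgs_tr, y_tr = _load_split_arrays(data, "train", config.image_size)
    imgs_va, y_va = _load_split_arrays(data, "val", config.image_size)
    if len(imgs_tr) == 0 or len(imgs_va) == 0:
        raise SpecificationError(
            f"train/val splits must be non-empty "
            f"(train={len(imgs_tr)}, val={len(imgs_va)})")
    normalizer = Normalizer.fit(imgs_tr)
    x_tr = normalizer.apply(imgs_tr)
    x_va = normalizer.apply(imgs_va)

    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    history = TrainHistory()
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate,
                        beta1=config.beta1, weight_decay=config.weight_decay)
    start_epoch = 0
    if resume is not None:
        ck_model, ck_norm, meta, arrays = load_checkpoint(resume)
        model.load_state_dict(ck_model.state_dict())
        optimizer.load_state_dict({k[len("opt/"):]: v
                                   for k, v in arrays.items()
                                   if k.startswith("opt/")})
        if ck_norm is not None:
            normalizer = ck_norm
            x_tr = normalizer.apply(imgs_tr)
            x_va = normalizer.apply(imgs_va)
        start_epoch = int(meta["epoch"])

    best = {"miou": -1.0}
    paths = {}
    if ckpt_dir:
        paths = {"last": str(ckpt_dir / "last.npz"),
                 "best": str(ckpt_dir / "best.npz")}

    def on_epoch_end(epoch, rec):
        if ckpt_dir:
            save_checkpoint(paths["last"], model, normalizer, config,
                            epoch, optimizer)
            if rec.get("val_miou", -1.0) > best["miou"]:
                best["miou"] = rec["val_miou"]
                save_checkpoint(paths["best"], model, normalizer, config,
                                epoch, optimizer)
            history.to_csv(ckpt_dir / "history.tsv")

    fit_arrays(model, x_tr, y_tr, config, x_va, y_va,
               history=history, optimizer=optimizer,
               start_epoch=start_epoch, on_epoch_end=on_epoch_end)
    return history, paths
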