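"""scikit-learn style estimator facade over the segmentation pipeline.

``RDSUnetSegmenter`` is the primary in-Python training surface: a
BaseEstimator with fit/predict/score that composes with sklearn model
selection. ``X`` is a stack of RGB images (n, H, W, 3) in 8-bit intensities
and ``y`` the matching class-index masks (n, H, W); ``score`` returns the
mean intersection-over-union of the predictions.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ShapeError, SpecificationError
from .evaluation import ConfusionMatrix, accumulate_confusion, miou
from .network import build_model, forward, preset
from .training import Normalizer, TrainConfig, fit_arrays


class RDSUnetSegmenter(BaseEstimator):
    """Per-pixel corn/weed classifier built on a preset segmentation network.

    Parameters mirror the training protocol defaults (Dice loss, Adam,
    lr 0.001, batch 4); ``epochs`` defaults low because the estimator is
    meant for programmatic experiments, not the full 100-epoch protocol.

    Fitted attributes: ``model_`` (the network), ``normalizer_`` (frozen
    per-channel standardization), ``history_`` (per-epoch records),
    ``classes_``.
    """

    def __init__(self, preset: str = "rds_unet", epochs: int = 10,
                 batch_size: int = 4, learning_rate: float = 1e-3,
                 beta1: float = 0.9, weight_decay: float = 1e-4,
                 include_background: bool = True, seed: int = 0,
                 max_steps: Optional[int] = None,
                 stop_at_train_miou: Optional[float] = None):
        self.preset = preset
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.weight_decay = weight_decay
        self.include_background = include_background
        self.seed = seed
        self.max_steps = max_steps
        self.stop_at_train_miou = stop_at_train_miou

    # -- helpers ---------------------------------------------------------
    @staticmethod
    def _check_X(X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ShapeError(f"X must be (n, H, W, 3), got {X.shape}")
        if X.shape[1] % 32 or X.shape[2] % 32:
            raise ShapeError("image height/width must be multiples of 32")
        return X

    def _config(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           learning_rate=self.learning_rate, beta1=self.beta1,
                           weight_decay=self.weight_decay,
                           include_background=self.include_background,
                           seed=self.seed, max_steps=self.max_steps,
                           stop_at_train_miou=self.stop_at_train_miou)

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None) -> "RDSUnetSegmenter":
        X = self._check_X(X)
        y = np.asarray(y)
        if y.shape != X.shape[:3]:
            raise ShapeError(f"y shape {y.shape} must match X {X.shape[:3]}")
        variant = preset(self.preset)
        self.model_ = build_model(variant, seed=self.seed)
        self.normalizer_ = Normalizer.fit(X)
        xt = self.normalizer_.apply(X)
        xv = yv = None
        if X_val is not None:
            xv = self.normalizer_.apply(self._check_X(X_val))
            yv = np.asarray(y_val)
        self.history_, _ = fit_arrays(self.model_, xt, y.astype(np.int64),
                                      self._config(), xv, yv)
        self.classes_ = np.arange(variant.n_classes)
        self.n_features_in_ = X.shape[1] * X.shape[2] * 3
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise SpecificationError("estimator is not fitted")
        X = self._check_X(X)
        xb = self.normalizer_.apply(X)
        out = []
        for i in range(0, len(xb), self.batch_size):
            out.append(forward(self.model_, xb[i:i + self.batch_size])
                       .argmax(axis=1))
        return np.concatenate(out).astype(np.uint8)

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise SpecificationError("estimator is not fitted")
        X = self._check_X(X)
        xb = self.normalizer_.apply(X)
        logits = np.concatenate(
            [forward(self.model_, xb[i:i + self.batch_size])
             for i in range(0, len(xb), self.batch_size)])
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def score(self, X, y) -> float:
        """Mean IoU of the predicted masks against ``y``."""
        pred = self.predict(X)
        cm = ConfusionMatrix()
        for p, t in zip(pred, np.asarray(y)):
            accumulate_confusion(p, t, cm)
        return miou(cm)
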