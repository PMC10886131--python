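"""Concurrent spatial and channel squeeze-and-excitation (scSE).

Two complementary recalibrations of a feature map x (C x H x W):

* channel excitation (cSE): a channel gate from global average pooling,
  g_c = sigmoid(W2 . relu(W1 . GAP(x))), with W1 halving the channel count
  (reduction ratio fixed at 2) and W2 restoring it; output x * g_c.
* spatial excitation (sSE): a per-position gate from a single-channel 1x1
  convolution, g_s = sigmoid(conv1x1(x)); output x * g_s.

The scSE output is the elementwise sum X_cSE + X_sSE. With all parameters
zero both gates are exactly 0.5, so scSE reduces to the identity — a useful
algebraic fixed point, checked by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import nn
from .errors import ShapeError


# ---------------------------------------------------------------------------
# functional single-map API
# ---------------------------------------------------------------------------

@dataclass
class ScseParams:
    """Parameters of one scSE block for a C-channel feature map.

    reduce_weights: (C, C_r) with C_r = max(1, C // 2); expand_weights:
    (C_r, C); spatial_weights: (C,) (the single-output 1x1 convolution);
    biases may be None (treated as zero).
    """

    reduce_weights: np.ndarray
    expand_weights: np.ndarray
    spatial_weights: np.ndarray
    reduce_bias: Optional[np.ndarray] = None
    expand_bias: Optional[np.ndarray] = None
    spatial_bias: float = 0.0

    @classmethod
    def zeros(cls, c: int) -> "ScseParams":
        cr = max(1, c // 2)
        return cls(np.zeros((c, cr)), np.zeros((cr, c)), np.zeros(c))


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _check(x: np.ndarray, c: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ShapeError("expected a C x H x W feature map")
    if x.shape[0] != c:
        raise ShapeError(f"feature map has {x.shape[0]} channels, "
                         f"params expect {c}")
    return x


def cse(x: np.ndarray, params: ScseParams) -> np.ndarray:
    """Channel recalibration: x scaled per-channel by the squeeze gate."""
    x = _check(x, params.reduce_weights.shape[0])
    g = x.mean(axis=(1, 2))                       # global average pool, (C,)
    z = g @ params.reduce_weights
    if params.reduce_bias is not None:
        z = z + params.reduce_bias
    z = np.maximum(z, 0.0)
    a = z @ params.expand_weights
    if params.expand_bias is not None:
        a = a + params.expand_bias
    gate = _sigmoid(a)                            # (C,), strictly in (0,1)
    return x * gate[:, None, None]


def sse(x: np.ndarray, params: ScseParams) -> np.ndarray:
    """Spatial recalibration: x scaled per-position by the 1x1-conv gate."""
    x = _check(x, params.spatial_weights.shape[0])
    gate = _sigmoid(np.tensordot(params.spatial_weights, x, axes=(0, 0))
                    + params.spatial_bias)        # (H, W)
    return x * gate[None]


def scse(x: np.ndarray, params: ScseParams) -> np.ndarray:
    """Concurrent recalibration: elementwise sum of cSE and sSE outputs."""
    return cse(x, params) + sse(x, params)


def spatial_gate(x: np.ndarray, params: ScseParams) -> np.ndarray:
    """The sSE gate map itself (H x W, single channel)."""
    x = _check(x, params.spatial_weights.shape[0])
    return _sigmoid(np.tensordot(params.spatial_weights, x, axes=(0, 0))
                    + params.spatial_bias)


# ---------------------------------------------------------------------------
# trainable layer
# ---------------------------------------------------------------------------

class SCSE(nn.Module):
    """Trainable scSE layer on batched (B, C, H, W) tensors.

    Gate weights get small random init (zero init would leave the channel
    branch at a gradient dead point: with W2 = 0 neither W1 nor b1 ever
    receives a gradient); biases start at zero.
    """

    def __init__(self, c: int, *, rng: Optional[np.random.Generator] = None,
                 zero_init: bool = False):
        super().__init__()
        cr = max(1, c // 2)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.fc_reduce = nn.Linear(c, cr, rng=rng, zero_init=zero_init)
        self.fc_expand = nn.Linear(cr, c, rng=rng, zero_init=zero_init)
        self.spatial = nn.Conv2d(c, 1, 1, rng=rng, zero_init=zero_init)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        b, c = x.shape[:2]
        g = x.mean(axis=(2, 3))                       # (B, C)
        gate_c = self.fc_expand(self.fc_reduce(g).relu()).sigmoid()
        y_cse = x * gate_c.reshape(b, c, 1, 1)
        y_sse = x * self.spatial(x).sigmoid()         # (B,1,H,W) broadcast
        return y_cse + y_sse

    def params_view(self) -> ScseParams:
        """Expose the learned weights in the functional parameter layout."""
        return ScseParams(
            reduce_weights=self.fc_reduce.weight.data.astype(np.float64),
            expand_weights=self.fc_expand.weight.data.astype(np.float64),
            spatial_weights=self.spatial.weight.data.reshape(-1).astype(np.float64),
            reduce_bias=self.fc_reduce.bias.data.astype(np.float64),
            expand_bias=self.fc_expand.bias.data.astype(np.float64),
            spatial_bias=float(self.spatial.bias.data[0]),
        )
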