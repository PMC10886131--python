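"""Deformable 2-D convolution with learnable fractional offsets.

A deformable convolution generalizes the standard cross-correlation

    y(p0) = sum_{p_n in R} w(p_n) * x(p0 + p_n)

by displacing every kernel tap p_n with a per-position learnable offset
Delta p_n:

    y(p0) = sum_{p_n in R} w(p_n) * x(p0 + p_n + Delta p_n)

The offsets are unconstrained reals, so the displaced sampling points are
resolved by bilinear interpolation; positions outside the feature map
contribute zero (consistent with zero same-padding). Offsets are shared
across input channels: one (dy, dx) pair per tap per spatial position,
giving an offset field of shape H x W x 2N with N = |R| kernel taps
(N = 9 for the 3x3 kernel used throughout the decoder).

Offset channel ordering is tap-major with dy before dx:
(dy_1, dx_1, ..., dy_N, dx_N), taps enumerated row-major over the kernel.
This ordering is frozen so that serialized weights stay portable.

This module holds the mathematical core on plain numpy arrays; the
trainable layer (offset branch + backprop through x, w and the offsets)
lives in :mod:`rdsunet.nn.modules` and calls the same routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.signal import correlate2d

from .errors import ShapeError


# ---------------------------------------------------------------------------
# kernel geometry
# ---------------------------------------------------------------------------

@dataclass
class KernelGrid:
    """The receptive-field region R of a square kernel plus its weights.

    ``weights`` has shape (C_out, C_in, k, k); taps are enumerated row-major
    so tap n corresponds to weights[..., n // k, n % k].
    """

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim == 2:  # single-channel convenience
            self.weights = self.weights[None, None]
        if self.weights.ndim != 4 or self.weights.shape[2] != self.weights.shape[3]:
            raise ShapeError("KernelGrid weights must be (C_out, C_in, k, k)")

    @property
    def kernel_size(self) -> int:
        return self.weights.shape[2]

    @property
    def n_taps(self) -> int:
        return self.kernel_size ** 2

    @property
    def taps(self) -> np.ndarray:
        """N x 2 integer (dy, dx) displacements, row-major; {-1,0,1}^2 for 3x3."""
        k = self.kernel_size
        half = k // 2
        return np.array([(i - half, j - half) for i in range(k) for j in range(k)])


def validate_offset_field(offsets: np.ndarray, n_taps: int) -> np.ndarray:
    """Check an H x W x 2N offset field: channel count and finiteness."""
    offsets = np.asarray(offsets, dtype=np.float64)
    if offsets.ndim != 3 or offsets.shape[2] != 2 * n_taps:
        raise ShapeError(
            f"offset field must be H x W x {2 * n_taps} for {n_taps} taps, "
            f"got shape {offsets.shape}")
    if not np.isfinite(offsets).all():
        raise ValueError("offset field contains non-finite values")
    return offsets


# ---------------------------------------------------------------------------
# reference operations
# ---------------------------------------------------------------------------

def standard_conv_ref(x: np.ndarray, grid: KernelGrid) -> np.ndarray:
    """Plain same-padded cross-correlation, the zero-offset reference.

    x: (C_in, H, W) (a bare (H, W) map is promoted to one channel).
    Returns (C_out, H, W).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    cout, cin = grid.weights.shape[:2]
    if x.shape[0] != cin:
        raise ShapeError(f"input has {x.shape[0]} channels, weights expect {cin}")
    out = np.zeros((cout, x.shape[1], x.shape[2]))
    for o in range(cout):
        for c in range(cin):
            out[o] += correlate2d(x[c], grid.weights[o, c],
                                  mode="same", boundary="fill", fillvalue=0.0)
    return out


def bilinear_sample(x: np.ndarray, p) -> np.ndarray:
    """Bilinearly sample a single-channel map at fractional (row, col) points.

    Out-of-bounds coordinates follow the zero-padding convention: each of the
    (at most four) integer neighbors contributes
    x[q] * max(0, 1-|dr|) * max(0, 1-|dc|) only while it lies on the grid.

    ``p`` is an array of shape (..., 2); a single (row, col) pair returns a
    scalar.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ShapeError("bilinear_sample expects a single-channel 2-D map")
    p = np.asarray(p, dtype=np.float64)
    if not np.isfinite(p).all():
        raise ValueError("non-finite sampling coordinate")
    scalar = p.ndim == 1
    pts = np.atleast_2d(p)
    h, w = x.shape
    py, px = pts[..., 0], pts[..., 1]
    y0, x0 = np.floor(py), np.floor(px)
    fy, fx = py - y0, px - x0
    val = np.zeros(py.shape)
    for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        yy = (y0 + dy).astype(np.int64)
        xx = (x0 + dx).astype(np.int64)
        wgt = (fy if dy else 1.0 - fy) * (fx if dx else 1.0 - fx)
        ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        val += np.where(ok, x[np.clip(yy, 0, h - 1), np.clip(xx, 0, w - 1)], 0.0) * wgt
    return float(val[0]) if scalar else val.reshape(p.shape[:-1])


# ---------------------------------------------------------------------------
# batched core (float32, used by both the functional API and the NN layer)
# ---------------------------------------------------------------------------

_NEIGHBORS = ((0, 0), (0, 1), (1, 0), (1, 1))


def _tap_vectors(k: int, dtype=np.float32) -> Tuple[np.ndarray, np.ndarray]:
    half = k // 2
    ty = np.array([i - half for i in range(k) for _ in range(k)], dtype=dtype)
    tx = np.array([j - half for _ in range(k) for j in range(k)], dtype=dtype)
    return ty.reshape(1, -1, 1, 1), tx.reshape(1, -1, 1, 1)


def _sampling_coords(offsets: np.ndarray, k: int):
    """offsets (B, 2N, H, W) -> absolute sampling rows/cols (B, N, H, W)."""
    b, c2n, h, w = offsets.shape
    n = k * k
    if c2n != 2 * n:
        raise ShapeError(f"offset tensor must have {2 * n} channels, got {c2n}")
    ty, tx = _tap_vectors(k, offsets.dtype)
    gy, gx = np.meshgrid(np.arange(h, dtype=offsets.dtype),
                         np.arange(w, dtype=offsets.dtype), indexing="ij")
    py = gy[None, None] + ty + offsets[:, 0::2]
    px = gx[None, None] + tx + offsets[:, 1::2]
    return py, px


def _gather(xf: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """xf: (B, C, H*W); idx: (B, M) int -> (B, C, M)."""
    return np.take_along_axis(xf, idx[:, None, :], axis=2)


def deform_conv_forward(x: np.ndarray, w: np.ndarray, offsets: np.ndarray,
                        bias: Optional[np.ndarray] = None,
                        want_cache: bool = False):
    """Batched deformable convolution forward pass.

    x: (B, C_in, H, W); w: (C_out, C_in, k, k); offsets: (B, 2N, H, W).
    Returns y (B, C_out, H, W) and, when requested, the cache for backward.
    """
    b, cin, h, wd = x.shape
    cout, cin_w, k, _ = w.shape
    if cin != cin_w:
        raise ShapeError(f"input has {cin} channels, weights expect {cin_w}")
    n = k * k
    py, px = _sampling_coords(offsets, k)                    # (B,N,H,W)
    y0, x0 = np.floor(py), np.floor(px)
    fy, fx = py - y0, px - x0
    xf = x.reshape(b, cin, h * wd)
    m = n * h * wd
    sampled = np.zeros((b, cin, n, h, wd), dtype=x.dtype)
    neigh = []
    for dy, dx in _NEIGHBORS:
        yy = (y0 + dy).astype(np.int64)
        xx = (x0 + dx).astype(np.int64)
        ok = ((yy >= 0) & (yy < h) & (xx >= 0) & (xx < wd)).astype(x.dtype)
        idx = (np.clip(yy, 0, h - 1) * wd + np.clip(xx, 0, wd - 1)).reshape(b, m)
        vals = _gather(xf, idx).reshape(b, cin, n, h, wd)
        wy = fy if dy else 1.0 - fy
        wx = fx if dx else 1.0 - fx
        sampled += vals * (ok * wy * wx)[:, None]
        if want_cache:
            neigh.append((dy, dx, idx, ok, vals))
    wre = w.reshape(cout, cin, n)
    y = np.einsum("bcnhw,ocn->bohw", sampled, wre, optimize=True)
    if bias is not None:
        y = y + bias.reshape(1, cout, 1, 1)
    cache = None
    if want_cache:
        cache = dict(sampled=sampled, neigh=neigh, fy=fy, fx=fx,
                     shape=(b, cin, h, wd), k=k)
    return y, cache


def deform_conv_backward(gy: np.ndarray, w: np.ndarray, cache: dict):
    """Gradients w.r.t. input, weights, offsets and bias.

    gy: (B, C_out, H, W). Returns (dx, dw, doffsets, dbias).
    """
    b, cin, h, wd = cache["shape"]
    k = cache["k"]
    n = k * k
    cout = w.shape[0]
    wre = w.reshape(cout, cin, n)
    sampled = cache["sampled"]
    fy, fx = cache["fy"], cache["fx"]

    dw = np.einsum("bohw,bcnhw->ocn", gy, sampled, optimize=True)
    dbias = gy.sum(axis=(0, 2, 3))
    dsampled = np.einsum("bohw,ocn->bcnhw", gy, wre, optimize=True)

    dxf = np.zeros((b, h * wd, cin), dtype=gy.dtype)
    grad_py = np.zeros((b, n, h, wd), dtype=gy.dtype)
    grad_px = np.zeros((b, n, h, wd), dtype=gy.dtype)
    m = n * h * wd
    for dy, dx, idx, ok, vals in cache["neigh"]:
        wy = fy if dy else 1.0 - fy
        wx = fx if dx else 1.0 - fx
        wgt = ok * wy * wx                                   # (B,N,H,W)
        contrib = (dsampled * wgt[:, None]).reshape(b, cin, m)
        contrib = contrib.transpose(0, 2, 1)                 # (B, M, Cin)
        for bi in range(b):
            np.add.at(dxf[bi], idx[bi], contrib[bi])
        # d(weight)/d(py) = +-wx, d/d(px) = +-wy (sign by neighbor side)
        sgn_y = 1.0 if dy else -1.0
        sgn_x = 1.0 if dx else -1.0
        masked_vals = (dsampled * vals).sum(axis=1)          # (B,N,H,W)
        grad_py += masked_vals * (ok * sgn_y * wx)
        grad_px += masked_vals * (ok * sgn_x * wy)

    dx = dxf.transpose(0, 2, 1).reshape(b, cin, h, wd)
    doff = np.empty((b, 2 * n, h, wd), dtype=gy.dtype)
    doff[:, 0::2] = grad_py
    doff[:, 1::2] = grad_px
    return dx, dw.reshape(w.shape), doff, dbias


# ---------------------------------------------------------------------------
# functional single-sample API
# ---------------------------------------------------------------------------

def deformable_conv(x: np.ndarray, grid: KernelGrid,
                    offsets: np.ndarray) -> np.ndarray:
    """Deformable convolution of one feature map.

    x: (C_in, H, W) or (H, W); offsets: H x W x 2N, channel order
    (dy_1, dx_1, ..., dy_N, dx_N) with taps row-major. Returns (C_out, H, W).
    With all-zero offsets this reduces exactly to :func:`standard_conv_ref`.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    offsets = validate_offset_field(offsets, grid.n_taps)
    off = offsets.transpose(2, 0, 1)[None]                   # (1, 2N, H, W)
    y, _ = deform_conv_forward(x[None], grid.weights, off)
    return y[0]
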