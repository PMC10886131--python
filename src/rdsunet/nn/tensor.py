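"""Minimal reverse-mode autodiff over numpy arrays.

This is the numerical core the segmentation networks are built on: a
``Tensor`` wrapping a float32 ndarray, a small set of differentiable
primitives (elementwise arithmetic with broadcasting, matmul, reductions,
2-D convolution via im2col + BLAS, grouped convolution, max pooling,
bilinear 2x upsampling, log-softmax), and topological-order backprop.

Design constraints:
  * float32 everywhere; gradients share dtype with data.
  * primitives cache only what their backward needs, and skip caching
    entirely under ``no_grad()`` so inference has no memory overhead.
  * broadcasting gradients are reduced back with ``_unbroadcast``.
"""

from __future__ import annotations

import contextlib
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != np.float32:
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data: np.ndarray = _as_f32(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) and grad_enabled()
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Tuple["Tensor", ...] = ()

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(_as_f32(grad))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- construction helper --------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: Sequence["Tensor"],
            backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if grad_enabled() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g, o.data.shape))

        return Tensor._op(self.data + o.data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor._op(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g * self.data, o.data.shape))

        return Tensor._op(self.data * o.data, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(-g * self.data / (o.data * o.data),
                                           o.data.shape))

        return Tensor._op(self.data / o.data, (self, o), bw)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._op(self.data ** p, (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._op(self.data[idx], (self,), bw)

    # -- matmul ----------------------------------------------------------
    def __matmul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ o.data.T)
            if o.requires_grad:
                o._accumulate(self.data.T @ g)

        return Tensor._op(self.data @ o.data, (self, o), bw)

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return Tensor._op(self.data * mask, (self,), bw)

    def sigmoid(self):
        from scipy.special import expit
        s = expit(self.data)

        def bw(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor._op(s, (self,), bw)

    def exp(self):
        e = np.exp(self.data)

        def bw(g):
            self._accumulate(g * e)

        return Tensor._op(e, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor._op(np.log(self.data), (self,), bw)

    def sqrt(self):
        r = np.sqrt(self.data)

        def bw(g):
            self._accumulate(g * 0.5 / r)

        return Tensor._op(r, (self,), bw)

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            gg = g
            if not keepdims and axis is not None:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                axes = tuple(a % self.data.ndim for a in axes)
                for a in sorted(axes):
                    gg = np.expand_dims(gg, a)
            self._accumulate(np.broadcast_to(gg, self.data.shape))

        return Tensor._op(self.data.sum(axis=axis, keepdims=keepdims,
                                        dtype=np.float32), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return Tensor._op(self.data.reshape(shape), (self,), bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor._op(self.data.transpose(axes), (self,), bw)

    def log_softmax(self, axis: int = 1):
        m = self.data.max(axis=axis, keepdims=True)
        z = self.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse
        p = np.exp(out)

        def bw(g):
            self._accumulate(g - p * g.sum(axis=axis, keepdims=True))

        return Tensor._op(out, (self,), bw)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def cat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._op(np.concatenate(datas, axis=axis), tensors, bw)


# ---------------------------------------------------------------------------
# conv2d (grouped) -- im2col + batched matmul
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int,
            hout: int, wout: int) -> np.ndarray:
    """(B,C,Hp,Wp) -> (B, C, kh*kw, hout*wout); one strided slice per tap."""
    b, c = xp.shape[:2]
    cols = np.empty((b, c, kh * kw, hout, wout), dtype=xp.dtype)
    t = 0
    for i in range(kh):
        for j in range(kw):
            cols[:, :, t] = xp[:, :, i:i + stride * hout:stride,
                               j:j + stride * wout:stride]
            t += 1
    return cols.reshape(b, c, kh * kw, hout * wout)


def _col2im(dcols: np.ndarray, xp_shape, kh: int, kw: int, stride: int,
            hout: int, wout: int) -> np.ndarray:
    b, c = xp_shape[:2]
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    dcols = dcols.reshape(b, c, kh * kw, hout, wout)
    t = 0
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * hout:stride,
                j:j + stride * wout:stride] += dcols[:, :, t]
            t += 1
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None, *,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation.

    x: (B, Cin, H, W); w: (Cout, Cin//groups, kh, kw); b: (Cout,).
    """
    bsz, cin, h, wdt = x.data.shape
    cout, cg, kh, kw = w.data.shape
    if cin != cg * groups:
        from ..errors import ShapeError
        raise ShapeError(
            f"conv2d: input has {cin} channels but weights expect "
            f"{cg * groups} ({groups} group(s) of {cg})")
    hout = (h + 2 * padding - kh) // stride + 1
    wout = (wdt + 2 * padding - kw) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2)) \
        if padding else x.data
    cols = _im2col(xp, kh, kw, stride, hout, wout)          # (B,Cin,KK,L)
    g = groups
    colsg = cols.reshape(bsz, g, cg * kh * kw, hout * wout)  # (B,G,CgKK,L)
    wg = w.data.reshape(g, cout // g, cg * kh * kw)          # (G,Coutg,CgKK)
    y = np.matmul(wg[None], colsg)                           # (B,G,Coutg,L)
    y = y.reshape(bsz, cout, hout, wout)
    if b is not None:
        y = y + b.data.reshape(1, cout, 1, 1)

    def bw(gy):
        gyg = gy.reshape(bsz, g, cout // g, hout * wout)
        if w.requires_grad:
            dw = np.matmul(gyg, colsg.transpose(0, 1, 3, 2)).sum(axis=0)
            w._accumulate(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gy.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcolsg = np.matmul(wg.transpose(0, 2, 1)[None], gyg)
            dxp = _col2im(dcolsg.reshape(bsz, cin, kh * kw, hout * wout),
                          xp.shape, kh, kw, stride, hout, wout)
            if padding:
                dxp = dxp[:, :, padding:padding + h, padding:padding + wdt]
            x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._op(y, parents, bw)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    bsz, c, h, w = x.data.shape
    hout = (h + 2 * padding - kernel) // stride + 1
    wout = (w + 2 * padding - kernel) // stride + 1
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
                    constant_values=-np.inf)
    else:
        xp = x.data
    cols = _im2col(xp, kernel, kernel, stride, hout, wout)  # (B,C,KK,L)
    arg = cols.argmax(axis=2)                               # (B,C,L)
    y = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0]

    def bw(gy):
        dcols = np.zeros_like(cols)
        np.put_along_axis(dcols, arg[:, :, None],
                          gy.reshape(bsz, c, 1, hout * wout), axis=2)
        dxp = _col2im(dcols, xp.shape, kernel, kernel, stride, hout, wout)
        if padding:
            dxp = dxp[:, :, padding:padding + h, padding:padding + w]
        x._accumulate(dxp)

    return Tensor._op(y.reshape(bsz, c, hout, wout), (x,), bw)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (align_corners=False)."""
    a = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        f = src - lo
        a[o, lo] += 1.0 - f
        a[o, hi] += f
    return a


_INTERP_CACHE: dict = {}


def upsample_bilinear(x: Tensor, factor: int = 2) -> Tensor:
    bsz, c, h, w = x.data.shape
    key = (h, w, factor)
    if key not in _INTERP_CACHE:
        _INTERP_CACHE[key] = (_interp_matrix(h * factor, h),
                              _interp_matrix(w * factor, w))
    ah, aw = _INTERP_CACHE[key]
    y = np.einsum("ij,bcjk,lk->bcil", ah, x.data, aw, optimize=True)

    def bw(gy):
        x._accumulate(np.einsum("ij,bcil,lk->bcjk", ah, gy, aw, optimize=True))

    return Tensor._op(y, (x,), bw)
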