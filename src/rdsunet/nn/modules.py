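"""Layer/module framework over the autodiff core.

Mirrors the familiar Module/parameters/state_dict conventions so the
segmentation networks read like their torch equivalents while running on
numpy. Weight init follows He-normal for convolutions/linears (fan-in),
zeros for biases.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from ..deformable import deform_conv_backward, deform_conv_forward
from ..errors import ShapeError
from .tensor import (Tensor, conv2d, grad_enabled, max_pool2d,
                     upsample_bilinear)


class Module:
    def __init__(self):
        self.training = True

    # -- introspection ---------------------------------------------------
    def named_children(self) -> Iterator[Tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for name, child in self.named_children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> List[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self.named_children():
            yield from child.named_buffers(prefix + name + ".")

    # -- mode ------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self.named_children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- serialization ---------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {name: p.data for name, p in self.named_parameters()}
        out.update({name: b for name, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name: True for name, _ in self.named_buffers()}
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict is missing keys: {sorted(missing)[:5]} ...")
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ShapeError(f"shape mismatch for {name}")
                params[name].data = arr.astype(np.float32, copy=True)
            elif name in buffers:
                # buffers live on nested modules; walk the path
                obj: Module = self
                *path, leaf = name.split(".")
                for part in path:
                    obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
                setattr(obj, leaf, arr.astype(np.float32, copy=True))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x

    def __getitem__(self, i):
        return self.mods[i]

    def __len__(self):
        return len(self.mods)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, *, stride: int = 1,
                 padding: Optional[int] = None, groups: int = 1,
                 bias: bool = True, rng: Optional[np.random.Generator] = None,
                 zero_init: bool = False):
        super().__init__()
        if cin % groups or cout % groups:
            raise ShapeError(
                f"channels ({cin}->{cout}) not divisible by groups={groups}")
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = (cin // groups) * k * k
        if zero_init:
            w = np.zeros((cout, cin // groups, k, k), np.float32)
        else:
            rng = rng if rng is not None else np.random.default_rng(0)
            w = _he_normal(rng, (cout, cin // groups, k, k), fan_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups)


class Linear(Module):
    def __init__(self, cin: int, cout: int, *, bias: bool = True,
                 rng: Optional[np.random.Generator] = None,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((cin, cout), np.float32)
        else:
            rng = rng if rng is not None else np.random.default_rng(0)
            w = _he_normal(rng, (cin, cout), cin)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    """Standard batch normalization with running statistics.

    Included per the reference ResNeXt design because random-init training
    at lr 1e-3 is not stable without it. Layers can be built norm-free for
    algebraic oracles.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)
        self._buffers = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(c) - self.running_mean)
            self.running_var += self.momentum * (
                var.data.reshape(c) - self.running_var)
            xhat = (x - mu) / ((var + self.eps).sqrt())
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.gamma.reshape(1, c, 1, 1) \
            + self.beta.reshape(1, c, 1, 1)


class MaxPool2d(Module):
    def __init__(self, k: int, stride: int, padding: int = 0):
        super().__init__()
        self.k, self.stride, self.padding = k, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.k, self.stride, self.padding)


class UpsampleBilinear(Module):
    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return upsample_bilinear(x, self.factor)


# ---------------------------------------------------------------------------
# deformable convolution layer
# ---------------------------------------------------------------------------

def deform_conv2d_op(x: Tensor, w: Tensor, offsets: Tensor,
                     b: Optional[Tensor] = None) -> Tensor:
    """Differentiable deformable convolution (autograd wrapper on the core)."""
    need = grad_enabled() and (x.requires_grad or w.requires_grad
                               or offsets.requires_grad
                               or (b is not None and b.requires_grad))
    y, cache = deform_conv_forward(x.data, w.data, offsets.data,
                                   None if b is None else b.data,
                                   want_cache=need)

    def bw(gy):
        dx, dw, doff, db = deform_conv_backward(gy, w.data, cache)
        if x.requires_grad:
            x._accumulate(dx)
        if w.requires_grad:
            w._accumulate(dw)
        if offsets.requires_grad:
            offsets._accumulate(doff)
        if b is not None and b.requires_grad:
            b._accumulate(db)

    parents = [x, w, offsets] + ([b] if b is not None else [])
    return Tensor._op(y, parents, bw)


class DeformableConv2d(Module):
    """3x3 deformable convolution with a zero-initialized offset branch.

    The offset branch is itself a same-padded 3x3 convolution producing
    2N = 18 channels; starting it at exact zero makes the layer equal to a
    standard convolution at initialization, from which the offsets are
    refined by backpropagation.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, *, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.k = k
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Tensor(_he_normal(rng, (cout, cin, k, k), cin * k * k),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) \
            if bias else None
        self.offset_conv = Conv2d(cin, 2 * k * k, 3, padding=1, zero_init=True)

    def offsets(self, x: Tensor) -> Tensor:
        return self.offset_conv(x)

    def forward(self, x: Tensor) -> Tensor:
        return deform_conv2d_op(x, self.weight, self.offsets(x), self.bias)
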