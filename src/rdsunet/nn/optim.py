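"""Adam optimizer with L2 weight decay (decay added to the gradient).

The update is fused into a single pass over memory with a numba kernel
when numba is importable (the update is bandwidth-bound on models of this
size); a vectorized numpy path computes the identical recurrence otherwise.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .tensor import Tensor

try:
    from numba import njit

    @njit(fastmath=False, cache=False)
    def _fused_update(p, g, m, v, b1, b2, alpha, shift, wd):
        for i in range(p.size):
            gi = g[i] + wd * p[i]
            m[i] = b1 * m[i] + (1.0 - b1) * gi
            v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
            p[i] -= alpha * m[i] / (np.sqrt(v[i]) + shift)

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba present in supported envs
    _HAVE_NUMBA = False


class Adam:
    def __init__(self, params: List[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.eps, self.wd = eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        # p -= lr/b1t * m / (sqrt(v/b2t)+eps), refactored so every pass is
        # in-place over one scratch buffer (the update is bandwidth-bound)
        alpha = self.lr * np.sqrt(b2t) / b1t
        shift = self.eps * np.sqrt(b2t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad  # safe to modify: cleared before the next backward
            if _HAVE_NUMBA:
                _fused_update(p.data.reshape(-1),
                              np.ascontiguousarray(g).reshape(-1),
                              m.reshape(-1), v.reshape(-1),
                              np.float32(self.b1), np.float32(self.b2),
                              np.float32(alpha), np.float32(shift),
                              np.float32(self.wd))
                continue
            t = np.empty_like(g)
            if self.wd:
                np.multiply(p.data, self.wd, out=t)
                g += t
            m *= self.b1
            np.multiply(g, 1.0 - self.b1, out=t)
            m += t
            v *= self.b2
            np.square(g, out=t)
            t *= (1.0 - self.b2)
            v += t
            np.sqrt(v, out=t)
            t += shift
            np.divide(m, t, out=t)
            t *= alpha
            p.data -= t

    # -- checkpoint support ---------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {"t": np.array(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"m{i}"] = m
            out[f"v{i}"] = v
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        self.t = int(state["t"])
        for i in range(len(self.m)):
            self.m[i] = state[f"m{i}"].copy()
            self.v[i] = state[f"v{i}"].copy()
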