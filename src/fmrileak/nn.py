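"""Minimal numpy neural-network engine for the two volumetric CNNs.

Implements exactly the layers the decoders need — valid-mode 2D/3D
convolution, Mish activation, non-overlapping max pooling, dense layers,
inverted dropout — plus softmax cross-entropy and Adam. Every layer has an
explicit ``backward`` that is gradient-checked against finite differences
in the test suite. Convolutions are computed as a sum of kernel-offset
``einsum`` contractions, which is fast at the volume sizes used here
(16^3) and keeps forward and backward symmetric and easy to audit.

All randomness (initialization, batching, dropout) flows from a single
``numpy`` Generator so training is reproducible from a seed on one thread.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)


# ---------------------------------------------------------------------------
# activations


def mish(x: np.ndarray) -> np.ndarray:
    """Mish activation, x * tanh(softplus(x)), evaluated stably."""
    x = np.asarray(x, dtype=float)
    return x * np.tanh(np.logaddexp(0.0, x))


def mish_grad(x: np.ndarray) -> np.ndarray:
    """d/dx mish(x) = tanh(sp) + x * (1 - tanh(sp)^2) * sigmoid(x)."""
    x = np.asarray(x, dtype=float)
    sp = np.logaddexp(0.0, x)
    t = np.tanh(sp)
    sig = 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable sigmoid
    return t + x * (1.0 - t * t) * sig


class Mish:
    def __init__(self) -> None:
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return mish(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * mish_grad(self._x)

    def params(self) -> List[Param]:
        return []


# ---------------------------------------------------------------------------
# convolutions (valid mode, stride 1)


class _ConvND:
    """Shared implementation for 2D/3D valid convolution, stride 1."""

    ndim: int

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel**self.ndim
        w_shape = (c_out, c_in) + (kernel,) * self.ndim
        self.w = Param("w", rng.standard_normal(w_shape) * np.sqrt(2.0 / fan_in))
        self.b = Param("b", np.zeros(c_out))
        self._x: np.ndarray | None = None

    def _offsets(self):
        k = self.kernel
        if self.ndim == 2:
            return [(i, j) for i in range(k) for j in range(k)]
        return [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]

    def _out_spatial(self, x_shape) -> Tuple[int, ...]:
        spatial = x_shape[2:]
        if len(spatial) != self.ndim:
            raise ValueError(f"expected {self.ndim + 2}D input, got shape {x_shape}")
        out = tuple(s - self.kernel + 1 for s in spatial)
        if any(s < 1 for s in out):
            raise ValueError(
                f"spatial shape {spatial} smaller than kernel {self.kernel}"
            )
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        n = x.shape[0]
        out_sp = self._out_spatial(x.shape)
        out = np.zeros((n, self.c_out) + out_sp)
        subscripts = "nchw,fc->nfhw" if self.ndim == 2 else "nchwd,fc->nfhwd"
        for off in self._offsets():
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, out_sp)
            )
            out += np.einsum(subscripts, x[sl], self.w.value[(slice(None), slice(None)) + off])
        out += self.b.value.reshape((1, -1) + (1,) * self.ndim)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        out_sp = dout.shape[2:]
        sum_axes = (0,) + tuple(range(2, 2 + self.ndim))
        self.b.grad += dout.sum(axis=sum_axes)
        dx = np.zeros_like(x)
        subs_w = "nfhw,nchw->fc" if self.ndim == 2 else "nfhwd,nchwd->fc"
        subs_x = "nfhw,fc->nchw" if self.ndim == 2 else "nfhwd,fc->nchwd"
        for off in self._offsets():
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, out_sp)
            )
            widx = (slice(None), slice(None)) + off
            self.w.grad[widx] += np.einsum(subs_w, dout, x[sl])
            dx[sl] += np.einsum(subs_x, dout, self.w.value[widx])
        return dx

    def params(self) -> List[Param]:
        return [self.w, self.b]

    @property
    def n_params(self) -> int:
        return self.w.value.size + self.b.value.size


class Conv2d(_ConvND):
    ndim = 2


class Conv3d(_ConvND):
    ndim = 3


# ---------------------------------------------------------------------------
# pooling


class MaxPool:
    """Non-overlapping max pooling with window ``size`` on all spatial axes.

    Trailing rows/columns that do not fill a window are dropped (floor
    semantics), receiving zero gradient.
    """

    def __init__(self, size: int = 2, ndim: int = 2):
        self.size, self.ndim = size, ndim
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = self.size
        spatial = x.shape[2:]
        out_sp = tuple(d // s for d in spatial)
        if any(d < 1 for d in out_sp):
            raise ValueError(f"spatial shape {spatial} too small for pool {s}")
        crop = tuple(slice(0, d * s) for d in out_sp)
        xc = x[(slice(None), slice(None)) + crop]
        new_shape = x.shape[:2]
        for d in out_sp:
            new_shape = new_shape + (d, s)
        xr = xc.reshape(new_shape)
        axes = tuple(3 + 2 * i for i in range(self.ndim))
        out = xr.max(axis=axes)
        # winner mask for backward (ties share the incoming gradient)
        expand = out
        for ax in axes:
            expand = np.expand_dims(expand, ax)
        winners = (xr == expand)
        self._cache = (x.shape, crop, new_shape, winners, axes)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, crop, new_shape, winners, axes = self._cache
        dexp = dout
        for ax in axes:
            dexp = np.expand_dims(dexp, ax)
        counts = winners.sum(axis=axes, keepdims=True)
        dxr = winners * (dexp / counts)
        dx = np.zeros(x_shape)
        dx[(slice(None), slice(None)) + crop] = dxr.reshape(
            dx[(slice(None), slice(None)) + crop].shape
        )
        return dx

    def params(self) -> List[Param]:
        return []


# ---------------------------------------------------------------------------
# dense / dropout / flatten


class Flatten:
    def __init__(self) -> None:
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params(self) -> List[Param]:
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param("w", rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in))
        self.b = Param("b", np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T

    def params(self) -> List[Param]:
        return [self.w, self.b]

    @property
    def n_params(self) -> int:
        return self.w.value.size + self.b.value.size


class Dropout:
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not (0.0 <= p < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p, self.rng = p, rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask

    def params(self) -> List[Param]:
        return []


class Sequential:
    def __init__(self, layers: Sequence):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> List[Param]:
        return [p for layer in self.layers for p in layer.params()]


# ---------------------------------------------------------------------------
# loss and optimizer


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(
    scores: np.ndarray, labels: np.ndarray
) -> Tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the scores."""
    n = scores.shape[0]
    p = softmax(scores)
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-300)))
    dscores = p.copy()
    dscores[np.arange(n), labels] -= 1.0
    return loss, dscores / n


class Adam:
    """Adam with an externally scheduled learning rate."""

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def get_state(params: Sequence[Param]) -> Dict[int, np.ndarray]:
    return {i: p.value.copy() for i, p in enumerate(params)}


def set_state(params: Sequence[Param], state: Dict[int, np.ndarray]) -> None:
    for i, p in enumerate(params):
        p.value[...] = state[i]
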