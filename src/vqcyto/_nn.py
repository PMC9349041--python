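"""Minimal CNN building blocks on numpy with explicit reverse-mode gradients.

Layers cache what their backward pass needs on ``forward`` and release it on
``backward``; the network is a static chain, so single-threaded alternation
of the two is sufficient.  Convolutions use 'same' padding with output side
``ceil(H / stride)``; weights are He-initialized from an explicit generator.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _same_pad(size: int, k: int, stride: int) -> tuple[int, int, int]:
    out = -(-size // stride)
    pad = max((out - 1) * stride + k - size, 0)
    return out, pad // 2, pad - pad // 2


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, scale, (cout, cin * k * k)))
        self.b = Param(np.zeros(cout))
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        bsz, c, h, w = x.shape
        k, s = self.k, self.stride
        ho, pt, pb = _same_pad(h, k, s)
        wo, pl, pr = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            bsz * ho * wo, c * k * k
        )
        y = cols @ self.w.value.T + self.b.value
        self._cache = (cols, x.shape, xp.shape, (ho, wo, pt, pl))
        return np.ascontiguousarray(
            y.reshape(bsz, ho, wo, self.cout).transpose(0, 3, 1, 2)
        )

    def backward(self, dy):
        cols, x_shape, xp_shape, (ho, wo, pt, pl) = self._cache
        self._cache = None
        bsz, c, h, w = x_shape
        k, s = self.k, self.stride
        dy_flat = dy.transpose(0, 2, 3, 1).reshape(bsz * ho * wo, self.cout)
        self.w.grad += dy_flat.T @ cols
        self.b.grad += dy_flat.sum(axis=0)
        dcols = dy_flat @ self.w.value
        dwin = dcols.reshape(bsz, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros(xp_shape, np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dwin[
                    ..., i, j
                ]
        return dxp[:, :, pt : pt + h, pl : pl + w]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        mask, self._mask = self._mask, None
        return dy * mask


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / nin), (nout, nin)))
        self.b = Param(np.zeros(nout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        x, self._x = self._x, None
        self.w.grad += dy.T @ x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class NearestResize(Layer):
    """Nearest-neighbor spatial resize to a fixed (H, W) target."""

    def __init__(self, target: tuple[int, int]):
        self.target = target
        self._src = None

    def forward(self, x):
        th, tw = self.target
        h, w = x.shape[2], x.shape[3]
        self._src = (h, w)
        self._iy = (np.arange(th) * h // th).astype(np.intp)
        self._ix = (np.arange(tw) * w // tw).astype(np.intp)
        return np.ascontiguousarray(x[:, :, self._iy[:, None], self._ix[None, :]])

    def backward(self, dy):
        h, w = self._src
        dx = np.zeros(dy.shape[:2] + (h, w), np.float32)
        np.add.at(dx, (slice(None), slice(None), self._iy[:, None], self._ix[None, :]), dy)
        return dx


class ResBlock(Layer):
    """conv3x3 - ReLU - conv3x3 with identity skip, ReLU on the sum."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.c1 = Conv2d(channels, channels, rng)
        self.r1 = ReLU()
        self.c2 = Conv2d(channels, channels, rng)
        self.r2 = ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        y = self.c2.forward(self.r1.forward(self.c1.forward(x)))
        return self.r2.forward(y + x)

    def backward(self, dy):
        d = self.r2.backward(dy)
        dx = self.c1.backward(self.r1.backward(self.c2.backward(d)))
        return dx + d


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean categorical cross entropy and its gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), targets] + 1e-30)))
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad.fill(0.0)

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
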