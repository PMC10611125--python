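"""Minimal numpy neural-network core: layers, Adam, softmax cross-entropy.

Supports exactly what the package needs — 2-D valid convolutions (im2col),
width-wise max pooling, dense layers with optional bias, dropout, and leaky
or plain rectifiers — with manual backprop and float32 arithmetic.  All
randomness flows through explicit ``numpy.random.Generator`` objects, so
training is bit-reproducible for a fixed seed and thread count.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D", "Dense", "ReLU", "LeakyReLU", "MaxPoolW", "Flatten", "Dropout",
    "Sequential", "Adam", "softmax", "softmax_xent",
]


class Layer:
    """Base layer; stateless layers only implement forward/backward."""

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs; gradients are overwritten in backward."""
        return []


class Conv2D(Layer):
    """Valid 2-D convolution via im2col; kernel (kh, kw) over (H, W)."""

    def __init__(self, in_f: int, out_f: int, kh: int, kw: int,
                 rng: np.random.Generator, bias: bool = True):
        fan_in = in_f * kh * kw
        scale = np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((out_f, fan_in)) * scale).astype(np.float32)
        self.b = np.zeros(out_f, dtype=np.float32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self.kh, self.kw = kh, kw
        self.in_f, self.out_f = in_f, out_f

    def forward(self, x, train, rng):
        b, c, h, w = x.shape
        if h < self.kh or w < self.kw:
            raise ValueError(
                f"kernel ({self.kh}, {self.kw}) exceeds input extent ({h}, {w})"
            )
        ho, wo = h - self.kh + 1, w - self.kw + 1
        cols = sliding_window_view(x, (self.kh, self.kw), axis=(2, 3))
        # (b, c, ho, wo, kh, kw) -> (c*kh*kw, b*ho*wo): one GEMM per layer
        cols = cols.transpose(1, 4, 5, 0, 2, 3).reshape(
            c * self.kh * self.kw, b * ho * wo)
        self._cols = np.ascontiguousarray(cols, dtype=np.float32)
        self._xshape = x.shape
        y = self.W @ self._cols                       # (out_f, b*ho*wo)
        if self.b is not None:
            y += self.b[:, None]
        y = y.reshape(self.out_f, b, ho, wo).transpose(1, 0, 2, 3)
        return np.ascontiguousarray(y)

    def backward(self, grad):
        b, o, ho, wo = grad.shape
        g = np.ascontiguousarray(grad.transpose(1, 0, 2, 3)).reshape(o, -1)
        self.dW[...] = g @ self._cols.T
        if self.b is not None:
            self.db[...] = g.sum(axis=1)
        dcols = (self.W.T @ g).reshape(self.in_f, self.kh, self.kw, b, ho, wo)
        dcols = dcols.transpose(3, 0, 1, 2, 4, 5)     # (b, c, kh, kw, ho, wo)
        dx = np.zeros(self._xshape, dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, :, i:i + ho, j:j + wo] += dcols[:, :, i, j]
        return dx

    def params(self):
        out = [(self.W, self.dW)]
        if self.b is not None:
            out.append((self.b, self.db))
        return out


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None

    def forward(self, x, train, rng):
        self._x = x
        y = x @ self.W
        if self.b is not None:
            y += self.b
        return y

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        if self.b is not None:
            self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        out = [(self.W, self.dW)]
        if self.b is not None:
            out.append((self.b, self.db))
        return out


class ReLU(Layer):
    def forward(self, x, train, rng):
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def forward(self, x, train, rng):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x).astype(np.float32)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad).astype(np.float32)


class MaxPoolW(Layer):
    """Max pooling of size ``k`` along the last (width) axis, stride ``k``.

    A trailing remainder narrower than ``k`` is discarded.
    """

    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x, train, rng):
        b, c, h, w = x.shape
        wp = w // self.k
        self._in_w = w
        xr = x[..., :wp * self.k].reshape(b, c, h, wp, self.k)
        if self.k == 2:
            a, bb = xr[..., 0], xr[..., 1]
            y = np.maximum(a, bb)
            if train:  # argmax semantics: ties resolve to the first element
                self._arg = (bb > a).astype(np.int8)
        else:
            y = xr.max(axis=-1)
            if train:
                self._arg = xr.argmax(axis=-1).astype(np.int8)
        return np.ascontiguousarray(y)

    def backward(self, grad):
        b, c, h, wp = grad.shape
        dxr = np.zeros((b, c, h, wp, self.k), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None].astype(np.intp),
                          grad[..., None], axis=-1)
        dx = np.zeros((b, c, h, self._in_w), dtype=np.float32)
        dx[..., :wp * self.k] = dxr.reshape(b, c, h, wp * self.k)
        return dx


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity when not training or when a pass supplies
    no generator."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0 or rng is None:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p).astype(np.float32)
        return x * self._mask / (1.0 - self.p)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask / (1.0 - self.p)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool = False, rng=None,
                tap: int | None = None):
        """Run the stack; if ``tap`` is given also return that layer's output."""
        tapped = None
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train, rng)
            if tap is not None and i == tap:
                tapped = x
        return (x, tapped) if tap is not None else x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for (p, g), m, v in zip(self.params, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray
                 ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)
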