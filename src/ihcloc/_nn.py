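"""Minimal numpy convolutional-network layers with forward and backward passes.

Supports exactly what the deep-feature stage needs: 3x3 same-padding
convolutions, non-overlapping max pooling, SELU/ReLU activations, global
average pooling, fully-connected layers, softmax cross-entropy, and momentum
SGD.  Arrays are NCHW float64.  This is deliberately small — it exists so
the convolutional feature extractors are runnable and trainable on a plain
CPU with no deep-learning framework present.
"""

from __future__ import annotations

import numpy as np

SELU_ALPHA = 1.6732632423543772
SELU_LAMBDA = 1.0507009873554805


class Layer:
    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or kxk) stride-1 convolution with same padding, via im2col."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * ksize * ksize
        # LeCun-normal initialization (the SELU-appropriate scheme)
        self.W = rng.normal(0.0, 1.0 / np.sqrt(fan_in), (out_ch, in_ch, ksize, ksize))
        self.b = np.zeros(out_ch)
        self.ksize = ksize
        self.pad = ksize // 2
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        N, C, H, Wd = x.shape
        k, p = self.ksize, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # win: (N, C, H, W, k, k) -> cols (N, C*k*k, H*W)
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(N, C * k * k, H * Wd)
        self._cols = cols
        self._xshape = x.shape
        Wm = self.W.reshape(self.W.shape[0], -1)
        out = np.einsum("fk,nkp->nfp", Wm, cols) + self.b[None, :, None]
        return out.reshape(N, -1, H, Wd)

    def backward(self, g):
        N, C, H, Wd = self._xshape
        k, p = self.ksize, self.pad
        F = self.W.shape[0]
        gf = g.reshape(N, F, H * Wd)
        Wm = self.W.reshape(F, -1)
        self.dW[...] = np.einsum("nfp,nkp->fk", gf, self._cols).reshape(self.W.shape)
        self.db[...] = gf.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfp->nkp", Wm, gf).reshape(N, C, k, k, H, Wd)
        dxp = np.zeros((N, C, H + 2 * p, Wd + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + Wd] += dcols[:, :, i, j]
        return dxp[:, :, p:p + H, p:p + Wd]


class MaxPool2d(Layer):
    """Non-overlapping kxk max pooling (input cropped to a multiple of k)."""

    def __init__(self, k: int = 2):
        self.k = k
        self._mask = None
        self._xshape = None
        self._crop = None

    def forward(self, x):
        k = self.k
        N, C, H, W = x.shape
        Hc, Wc = (H // k) * k, (W // k) * k
        xc = x[:, :, :Hc, :Wc]
        self._xshape = x.shape
        self._crop = (Hc, Wc)
        xr = xc.reshape(N, C, Hc // k, k, Wc // k, k)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, g):
        k = self.k
        N, C, H, W = self._xshape
        Hc, Wc = self._crop
        # split gradient evenly across tied maxima
        counts = self._mask.sum(axis=(3, 5), keepdims=True)
        gr = (g[:, :, :, None, :, None] * self._mask) / counts
        dx = np.zeros((N, C, H, W))
        dx[:, :, :Hc, :Wc] = gr.reshape(N, C, Hc, Wc)
        return dx


class SELU(Layer):
    def __init__(self):
        self._x = None

    def forward(self, x):
        self._x = x
        return SELU_LAMBDA * np.where(x > 0, x, SELU_ALPHA * (np.exp(x) - 1.0))

    def backward(self, g):
        x = self._x
        return g * SELU_LAMBDA * np.where(x > 0, 1.0, SELU_ALPHA * np.exp(x))


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C): each feature map reduced to one pixel."""

    def __init__(self):
        self._xshape = None

    def forward(self, x):
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        N, C, H, W = self._xshape
        return np.broadcast_to(g[:, :, None, None], (N, C, H, W)) / (H * W)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, 1.0 / np.sqrt(in_dim), (out_dim, in_dim))
        self.b = np.zeros(out_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, g):
        self.dW[...] = g.T @ self._x
        self.db[...] = g.sum(axis=0)
        return g @ self.W


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    loss = float(-np.log(p[np.arange(n), y] + 1e-12).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class SGD:
    """Momentum SGD over a (params, grads) pairing."""

    def __init__(self, params, grads, lr: float = 1e-3, momentum: float = 0.9):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.momentum = momentum
        self.v = [np.zeros_like(p) for p in params]

    def step(self):
        for p, g, v in zip(self.params, self.grads, self.v):
            v *= self.momentum
            v -= self.lr * g
            p += v
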