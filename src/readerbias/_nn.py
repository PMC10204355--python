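"""Minimal NumPy neural-network core: layers, a small CNN, and Adam.

Forward passes return (output, cache) and backward passes consume the cache,
so a network can run several forward passes (e.g. the two augmented views of a
consistency-regularized batch) before any backward pass. Parameter gradients
from multiple passes are simply summed.

All arrays are channel-first: images are (N, C, H, W).
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------- conv 3x3

DTYPE = np.float32  # training precision; float64 gains nothing for SGD here


class Conv3x3:
    """3x3 stride-1 'same' convolution with bias.

    Implemented as nine shifted GEMMs on a channels-last padded copy of the
    input -- one (N*H*W, C) @ (C, F) product per kernel offset -- which avoids
    materializing the 9x-larger im2col patch matrix. Weights are stored as a
    (C*9, F) matrix whose rows are ordered (channel, ki, kj).
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)).astype(
            DTYPE
        )
        self.b = np.zeros(c_out, dtype=DTYPE)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray):
        n, c, h, w = x.shape
        f = self.w.shape[1]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        xt = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))  # (N, H+2, W+2, C)
        wr = self.w.reshape(c, 3, 3, f)
        out = np.empty((n, h, w, f), dtype=x.dtype)
        out[:] = self.b
        for i in range(3):
            for j in range(3):
                out += xt[:, i : i + h, j : j + w, :] @ np.ascontiguousarray(
                    wr[:, i, j, :]
                )
        return out.transpose(0, 3, 1, 2), (xt, x.shape)

    def backward(self, dout: np.ndarray, cache):
        xt, x_shape = cache
        n, c, h, w = x_shape
        f = dout.shape[1]
        dt = np.ascontiguousarray(dout.transpose(0, 2, 3, 1))  # (N, H, W, F)
        wr = self.w.reshape(c, 3, 3, f)
        dw = np.empty((c, 3, 3, f), dtype=self.w.dtype)
        dxt = np.zeros_like(xt)
        for i in range(3):
            for j in range(3):
                window = xt[:, i : i + h, j : j + w, :]
                dw[:, i, j, :] = np.tensordot(window, dt, axes=([0, 1, 2], [0, 1, 2]))
                dxt[:, i : i + h, j : j + w, :] += dt @ np.ascontiguousarray(
                    wr[:, i, j, :].T
                )
        db = dt.sum(axis=(0, 1, 2))
        dx = dxt[:, 1 : 1 + h, 1 : 1 + w, :].transpose(0, 3, 1, 2)
        return dx, [dw.reshape(self.w.shape), db]


class ReLU:
    params: list = []

    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, dout, mask):
        return dout * mask, []


class MaxPool2:
    """2x2 max pooling; ties share the gradient equally."""

    params: list = []

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        return out, (xr, out)

    def backward(self, dout, cache):
        xr, out = cache
        mask = xr == out[:, :, :, None, :, None]
        mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        dxr = mask * dout[:, :, :, None, :, None]
        n, c, h2, _, w2, _ = xr.shape
        return dxr.reshape(n, c, h2 * 2, w2 * 2), []


class GlobalAvgPool:
    params: list = []

    def forward(self, x):
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, dout, x_shape):
        n, c, h, w = x_shape
        dx = np.broadcast_to(dout[:, :, None, None], x_shape) / (h * w)
        return dx.copy(), []


class Flatten:
    params: list = []

    def forward(self, x):
        return x.reshape(len(x), -1), x.shape

    def backward(self, dout, x_shape):
        return dout.reshape(x_shape), []


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)).astype(DTYPE)
        self.b = np.zeros(d_out, dtype=DTYPE)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        return x @ self.w + self.b, x

    def backward(self, dout, x):
        return dout @ self.w.T, [x.T @ dout, dout.sum(axis=0)]


# ---------------------------------------------------------------- network

class SmallCNN:
    """Three conv blocks (each conv-relu-pool) and a linear two-class head.

    Two heads are available: ``flatten`` (default) keeps the 4x-downsampled
    spatial map, giving the position-specific weights a small network needs to
    be able to memorize individual training images — the overfitting behavior
    under label noise that full-scale CNNs exhibit; ``gap`` applies global
    average pooling first, a translation-invariant and much lower-capacity
    alternative. Sized for 32x32 inputs at desk scale; any side divisible by 8
    works.
    """

    def __init__(
        self,
        in_channels: int = 3,
        channels: tuple[int, int, int] = (8, 16, 32),
        n_classes: int = 2,
        seed: int = 0,
        input_side: int = 32,
        head: str = "flatten",
    ):
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels
        self.layers = [
            Conv3x3(in_channels, c1, rng),
            ReLU(),
            MaxPool2(),
            Conv3x3(c1, c2, rng),
            ReLU(),
            MaxPool2(),
            Conv3x3(c2, c3, rng),
            ReLU(),
            MaxPool2(),
        ]
        if head == "gap":
            self.layers += [GlobalAvgPool(), Linear(c3, n_classes, rng)]
        elif head == "flatten":
            side = input_side // 8
            self.layers += [Flatten(), Linear(c3 * side * side, n_classes, rng)]
        else:
            raise ValueError(f"head must be 'flatten' or 'gap', got {head!r}")

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray):
        """Return (logits, caches). ``x`` is (N, C, H, W)."""
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x)
            caches.append(cache)
        return x, caches

    def backward(self, dlogits: np.ndarray, caches) -> list[np.ndarray]:
        """Gradients of every parameter, aligned with :attr:`params`."""
        grads_per_layer = []
        d = dlogits
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            d, g = layer.backward(d, cache)
            grads_per_layer.append(g)
        grads: list[np.ndarray] = []
        for g in reversed(grads_per_layer):
            grads.extend(g)
        return grads

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax class probabilities, (N, n_classes), without caching."""
        outs = []
        for i in range(0, len(x), batch_size):
            logits, _ = self.forward(x[i : i + batch_size])
            outs.append(softmax(logits))
        return np.concatenate(outs, axis=0)

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
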