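"""Minimal CNN engine: valid convolution, pooling, dense layers, Adam.

Purpose-built for the Siamese pair scorer in this package.  Tensors are
(N, C, H, W) float64; convolutions are "valid" (no padding) with the shape
rule out = floor((in - filter)/stride) + 1, matching the architecture
tables used throughout.  Forward passes return (output, cache) so that a
weight-sharing twin network can run two branches through the same layer
objects and back-propagate each branch with its own cache; gradients
accumulate across branches.

Only what the package needs is implemented: grouped valid convolution,
non-overlapping max pooling (stride = pool size, remainder cropped),
ReLU / leaky ReLU, inverted dropout, a dense layer, and Adam.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: weight initialization scale (narrow Gaussian)
INIT_SIGMA = 0.01


class Layer:
    """Base class: stateless forward/backward plus named params and grads."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, dy: np.ndarray, cache) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Valid 2D convolution (cross-correlation), optionally grouped."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, groups: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must divide evenly into groups")
        self.cin, self.cout = in_channels, out_channels
        self.k, self.stride, self.groups = kernel, stride, groups
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, INIT_SIGMA,
                       size=(out_channels, in_channels // groups, kernel, kernel))
        self.params = {"W": w, "b": np.zeros(out_channels)}
        self.zero_grads()

    def _forward_one(self, x: np.ndarray, w: np.ndarray, b: np.ndarray):
        n, c, h, wdt = x.shape
        k, s = self.k, self.stride
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        oh, ow = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        y = cols @ w.reshape(w.shape[0], -1).T + b
        return y.reshape(n, oh, ow, w.shape[0]).transpose(0, 3, 1, 2), cols, (oh, ow)

    def forward(self, x, train=False, rng=None):
        h, wdt = x.shape[2], x.shape[3]
        if h < self.k or wdt < self.k:
            raise ValueError(f"input {h}x{wdt} smaller than {self.k}x{self.k} filter")
        if self.groups == 1:
            y, cols, ohw = self._forward_one(x, self.params["W"], self.params["b"])
            return y, (x.shape, [cols], ohw)
        cg_in, cg_out = self.cin // self.groups, self.cout // self.groups
        outs, col_list = [], []
        for g in range(self.groups):
            wg = self.params["W"][g * cg_out:(g + 1) * cg_out]
            bg = self.params["b"][g * cg_out:(g + 1) * cg_out]
            yg, cols, ohw = self._forward_one(x[:, g * cg_in:(g + 1) * cg_in], wg, bg)
            outs.append(yg)
            col_list.append(cols)
        return np.concatenate(outs, axis=1), (x.shape, col_list, ohw)

    def backward(self, dy, cache):
        x_shape, col_list, (oh, ow) = cache
        n = x_shape[0]
        k, s = self.k, self.stride
        cg_in, cg_out = self.cin // self.groups, self.cout // self.groups
        dx = np.zeros(x_shape)
        for g in range(self.groups):
            dyg = dy[:, g * cg_out:(g + 1) * cg_out]
            dym = dyg.transpose(0, 2, 3, 1).reshape(n * oh * ow, cg_out)
            wg = self.params["W"][g * cg_out:(g + 1) * cg_out]
            self.grads["W"][g * cg_out:(g + 1) * cg_out] += (
                dym.T @ col_list[g]
            ).reshape(cg_out, cg_in, k, k)
            self.grads["b"][g * cg_out:(g + 1) * cg_out] += dym.sum(axis=0)
            dcols = (dym @ wg.reshape(cg_out, -1)).reshape(n, oh, ow, cg_in, k, k)
            dxg = dx[:, g * cg_in:(g + 1) * cg_in]
            for i in range(k):
                for j in range(k):
                    dxg[:, :, i:i + oh * s:s, j:j + ow * s:s] += (
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
        return dx


class MaxPool2D(Layer):
    """Non-overlapping max pool; stride = pool size; remainder cropped."""

    def __init__(self, size: int) -> None:
        super().__init__()
        self.size = size

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        s = self.size
        oh, ow = h // s, w // s
        if oh < 1 or ow < 1:
            raise ValueError(f"input {h}x{w} too small for {s}x{s} pool")
        xc = x[:, :, :oh * s, :ow * s]
        win = xc.reshape(n, c, oh, s, ow, s).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, oh, ow, s * s)
        idx = win.argmax(axis=-1)
        y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        return y, (x.shape, idx)

    def backward(self, dy, cache):
        x_shape, idx = cache
        n, c, h, w = x_shape
        s = self.size
        oh, ow = h // s, w // s
        dwin = np.zeros((n, c, oh, ow, s * s))
        np.put_along_axis(dwin, idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros(x_shape)
        dx[:, :, :oh * s, :ow * s] = (
            dwin.reshape(n, c, oh, ow, s, s).transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, oh * s, ow * s)
        )
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        return np.maximum(x, 0.0), x > 0

    def backward(self, dy, cache):
        return dy * cache


class LeakyReLU(Layer):
    """max(x, 0) + a * min(x, 0); slope a applies to negative inputs."""

    def __init__(self, slope: float = 0.01) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x, train=False, rng=None):
        return np.where(x >= 0, x, self.slope * x), x >= 0

    def backward(self, dy, cache):
        return np.where(cache, dy, self.slope * dy)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float = 0.5) -> None:
        super().__init__()
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            return x, None
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask, mask

    def backward(self, dy, cache):
        return dy if cache is None else dy * cache


class Dense(Layer):
    """Fully connected layer; flattens its input."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": rng.normal(0.0, INIT_SIGMA, size=(out_features, in_features)),
            "b": np.zeros(out_features),
        }
        self.zero_grads()

    def forward(self, x, train=False, rng=None):
        flat = x.reshape(x.shape[0], -1)
        if flat.shape[1] != self.params["W"].shape[1]:
            raise ValueError(
                f"dense layer expects {self.params['W'].shape[1]} inputs, got {flat.shape[1]}"
            )
        return flat @ self.params["W"].T + self.params["b"], (flat, x.shape)

    def backward(self, dy, cache):
        flat, x_shape = cache
        self.grads["W"] += dy.T @ flat
        self.grads["b"] += dy.sum(axis=0)
        return (dy @ self.params["W"]).reshape(x_shape)


class Sequential:
    """An ordered stack of layers with explicit caches per pass."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x, train=train, rng=rng)
            caches.append(cache)
        return x, caches

    def backward(self, dy, caches):
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(dy, cache)
        return dy

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                yield (li, name), layer.params[name], layer.grads[name]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable sigmoid, clamped into the open interval (0, 1)
    so pair scores stay strictly inside it even when the logit saturates."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return np.clip(out, 1e-300, 1.0 - 1e-16)


class Adam:
    """Adam with bias correction; decay factors follow the training defaults."""

    def __init__(self, learning_rate: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.99, eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, named_params) -> None:
        self.t += 1
        for key, param, grad in named_params:
            if key not in self.m:
                self.m[key] = np.zeros_like(param)
                self.v[key] = np.zeros_like(param)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * grad
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * grad * grad
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
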