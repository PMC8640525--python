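"""Minimal deterministic feed-forward layers (numpy).

Only what the degeneration experiments need: 2-D convolution ("same"
padding, stride 1), 2x2 max pooling, dense layers with optional ReLU,
inverted dropout, and flatten.  Forward passes cache what backward needs;
all randomness (dropout masks) is drawn from an explicitly passed
generator so training is a pure function of the seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import InvalidArgumentError


class Layer:
    """Base layer: stateless unless it owns parameters."""

    name: str = ""

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


class Conv2D(Layer):
    """3x3 (by default) convolution, stride 1, zero "same" padding.

    Weights: ``kernel`` of shape (kh, kw, in_ch, out_ch), ``bias`` (out_ch,).
    """

    def __init__(
        self,
        name: str,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        activation: str | None = "relu",
        rng: np.random.Generator | None = None,
    ):
        self.name = name
        self.activation = activation
        kh = kw = kernel_size
        fan_in = kh * kw * in_channels
        rng = rng or np.random.default_rng(0)
        # He-normal init suits the ReLU nonlinearity
        self.kernel = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kh, kw, in_channels, out_channels))
        self.bias = np.zeros(out_channels)
        self.d_kernel = np.zeros_like(self.kernel)
        self.d_bias = np.zeros_like(self.bias)
        self._cache = None

    def forward(self, x, training=False, rng=None):
        kh, kw, _, _ = self.kernel.shape
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N,H,W,C,kh,kw)
        z = np.einsum("nhwcuv,uvco->nhwo", win, self.kernel, optimize=True) + self.bias
        a = _relu(z) if self.activation == "relu" else z
        self._cache = (win, z)
        return a

    def backward(self, grad_out):
        win, z = self._cache
        if self.activation == "relu":
            grad_out = grad_out * (z > 0)
        self.d_kernel = np.einsum("nhwcuv,nhwo->uvco", win, grad_out, optimize=True)
        self.d_bias = grad_out.sum(axis=(0, 1, 2))
        kh, kw, _, _ = self.kernel.shape
        ph, pw = kh // 2, kw // 2
        gp = np.pad(grad_out, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        gwin = sliding_window_view(gp, (kh, kw), axis=(1, 2))  # (N,H,W,O,kh,kw)
        flipped = self.kernel[::-1, ::-1]  # (kh,kw,C,O)
        return np.einsum("nhwouv,uvco->nhwc", gwin, flipped, optimize=True)

    def params(self):
        return {"kernel": self.kernel, "bias": self.bias}

    def grads(self):
        return {"kernel": self.d_kernel, "bias": self.d_bias}


class MaxPool2D(Layer):
    """2x2 non-overlapping max pooling.

    Backward splits the gradient equally among tied maxima inside a
    window; ties have measure zero for continuous inputs.
    """

    def __init__(self, pool: int = 2):
        self.pool = pool
        self._cache = None

    def forward(self, x, training=False, rng=None):
        p = self.pool
        n, h, w, c = x.shape
        if h % p or w % p:
            raise InvalidArgumentError(f"spatial dims {(h, w)} not divisible by pool {p}")
        r = x.reshape(n, h // p, p, w // p, p, c)
        y = r.max(axis=(2, 4))
        self._cache = (r, y, x.shape)
        return y

    def backward(self, grad_out):
        r, y, shape = self._cache
        mask = r == y[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        g = mask * (grad_out[:, :, None, :, None, :] / counts)
        return g.reshape(shape)


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class Dense(Layer):
    """Fully-connected layer: ``a = act(x @ kernel + bias)``."""

    def __init__(
        self,
        name: str,
        in_features: int,
        out_features: int,
        activation: str | None = "relu",
        rng: np.random.Generator | None = None,
    ):
        self.name = name
        self.activation = activation
        rng = rng or np.random.default_rng(0)
        limit = np.sqrt(6.0 / (in_features + out_features))  # Glorot uniform
        self.kernel = rng.uniform(-limit, limit, size=(in_features, out_features))
        self.bias = np.zeros(out_features)
        self.d_kernel = np.zeros_like(self.kernel)
        self.d_bias = np.zeros_like(self.bias)
        self._cache = None

    def forward(self, x, training=False, rng=None):
        z = x @ self.kernel + self.bias
        a = _relu(z) if self.activation == "relu" else z
        self._cache = (x, z)
        return a

    def backward(self, grad_out):
        x, z = self._cache
        if self.activation == "relu":
            grad_out = grad_out * (z > 0)
        self.d_kernel = x.T @ grad_out
        self.d_bias = grad_out.sum(axis=0)
        return grad_out @ self.kernel.T

    def params(self):
        return {"kernel": self.kernel, "bias": self.bias}

    def grads(self):
        return {"kernel": self.d_kernel, "bias": self.d_bias}


class Dropout(Layer):
    """Inverted dropout: active only when ``training=True`` and a rng is given."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise InvalidArgumentError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise InvalidArgumentError("training-mode dropout requires a generator")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad_out):
        if self._mask is None:
            return grad_out
        return grad_out * self._mask
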