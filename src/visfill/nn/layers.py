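"""Minimal convolutional layer library (numpy, NHWC, manual backprop).

Provides exactly the pieces the inpainting encoder/decoder and the
classification-network baseline need: strided convolution, transposed
convolution, batch normalization, ReLU / leaky-ReLU / sigmoid, and inverted
dropout.  All layers expose ``forward(x, training)`` / ``backward(dy)`` and a
``params()`` list of :class:`Param` so a generic optimizer can update them.

Arrays are ``(batch, height, width, channels)`` float64.  Gradients are exact
(verified against central finite differences in the test suite); there is no
autodiff — each layer implements its own adjoint.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "Identity",
    "Dropout",
    "make_activation",
    "conv_out_size",
    "tconv_out_size",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def conv_out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def tconv_out_size(n: int, k: int, s: int, p: int) -> int:
    return (n - 1) * s + k - 2 * p


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    """(N, Hp, Wp, C) -> (N, oh, ow, k, k, C) view-based patch extraction."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (N, Hp-k+1, Wp-k+1, C, k, k)
    win = win[:, ::s, ::s]
    return np.ascontiguousarray(np.moveaxis(win, 3, 5))  # (N, oh, ow, k, k, C)


class Conv2d(Layer):
    """2-D convolution (cross-correlation), stride ``s``, symmetric zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 4, stride: int = 2,
                 padding: int = 1, rng: np.random.Generator | None = None,
                 init_scale: float = 0.05, name: str = "conv"):
        if kernel < 1 or stride < 1:
            raise ValueError(f"{name}: kernel and stride must be positive, got k={kernel} s={stride}")
        rng = rng or np.random.default_rng(0)
        self.k, self.s, self.p = kernel, stride, padding
        self.in_ch, self.out_ch = in_ch, out_ch
        w = rng.normal(0.0, init_scale, size=(kernel, kernel, in_ch, out_ch))
        self.w = Param(f"{name}.w", w)
        self.b = Param(f"{name}.b", np.zeros(out_ch))
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        k, s, p = self.k, self.s, self.p
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        cols = _im2col(xp, k, s)  # (N, oh, ow, k, k, C)
        self._cols = cols
        self._xshape = x.shape
        n, oh, ow = cols.shape[:3]
        y = cols.reshape(n * oh * ow, -1) @ self.w.value.reshape(-1, self.out_ch)
        return y.reshape(n, oh, ow, self.out_ch) + self.b.value

    def backward(self, dy):
        k, s, p = self.k, self.s, self.p
        cols, xshape = self._cols, self._xshape
        n, oh, ow = cols.shape[:3]
        dy_flat = dy.reshape(n * oh * ow, self.out_ch)
        self.w.grad += (cols.reshape(n * oh * ow, -1).T @ dy_flat).reshape(self.w.value.shape)
        self.b.grad += dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.w.value.reshape(-1, self.out_ch).T).reshape(n, oh, ow, k, k, self.in_ch)
        hpad, wpad = xshape[1] + 2 * p, xshape[2] + 2 * p
        dxp = np.zeros((n, hpad, wpad, self.in_ch))
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki:ki + oh * s:s, kj:kj + ow * s:s, :] += dcols[:, :, :, ki, kj, :]
        return dxp[:, p:hpad - p, p:wpad - p, :] if p else dxp


class ConvTranspose2d(Layer):
    """Transposed (fractionally strided) convolution — the adjoint of Conv2d."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 4, stride: int = 2,
                 padding: int = 1, rng: np.random.Generator | None = None,
                 init_scale: float = 0.05, name: str = "tconv"):
        if kernel < 1 or stride < 1:
            raise ValueError(f"{name}: kernel and stride must be positive")
        rng = rng or np.random.default_rng(0)
        self.k, self.s, self.p = kernel, stride, padding
        self.in_ch, self.out_ch = in_ch, out_ch
        w = rng.normal(0.0, init_scale, size=(kernel, kernel, in_ch, out_ch))
        self.w = Param(f"{name}.w", w)
        self.b = Param(f"{name}.b", np.zeros(out_ch))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        k, s, p = self.k, self.s, self.p
        self._x = x
        n, ih, iw, _ = x.shape
        ohp = (ih - 1) * s + k  # padded output size
        owp = (iw - 1) * s + k
        yp = np.zeros((n, ohp, owp, self.out_ch))
        xw = x.reshape(n * ih * iw, self.in_ch)
        for ki in range(k):
            for kj in range(k):
                contrib = (xw @ self.w.value[ki, kj]).reshape(n, ih, iw, self.out_ch)
                yp[:, ki:ki + ih * s:s, kj:kj + iw * s:s, :] += contrib
        y = yp[:, p:ohp - p, p:owp - p, :] if p else yp
        return y + self.b.value

    def backward(self, dy):
        k, s, p = self.k, self.s, self.p
        x = self._x
        n, ih, iw, _ = x.shape
        ohp = (ih - 1) * s + k
        owp = (iw - 1) * s + k
        dyp = np.pad(dy, ((0, 0), (p, p), (p, p), (0, 0))) if p else dy
        self.b.grad += dy.reshape(-1, self.out_ch).sum(axis=0)
        dx = np.zeros_like(x)
        xw = x.reshape(n * ih * iw, self.in_ch)
        for ki in range(k):
            for kj in range(k):
                patch = dyp[:, ki:ki + ih * s:s, kj:kj + iw * s:s, :].reshape(n * ih * iw, self.out_ch)
                self.w.grad[ki, kj] += xw.T @ patch
                dx += (patch @ self.w.value[ki, kj].T).reshape(n, ih, iw, self.in_ch)
        return dx
        # (dyp slices always have exactly ih x iw elements because ohp = (ih-1)s + k)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W).

    Batch statistics during training (with running-average updates); frozen
    running statistics at inference.
    """

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(ch))
        self.beta = Param(f"{name}.beta", np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        if training:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, training, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, inv, training, shape = self._cache
        m = shape[0] * shape[1] * shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        g = self.gamma.value
        if not training:
            return dy * g * inv
        dxhat = dy * g
        return (inv / m) * (m * dxhat - dxhat.sum(axis=(0, 1, 2))
                            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)))


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Identity(Layer):
    def forward(self, x, training=False):
        return x

    def backward(self, dy):
        return dy


class Dropout(Layer):
    """Inverted dropout; a no-op at inference and when rate == 0."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


_ACTIVATIONS = {
    "relu": ReLU,
    "leaky_relu": LeakyReLU,
    "sigmoid": Sigmoid,
    "linear": Identity,
}


def make_activation(kind: str) -> Layer:
    try:
        return _ACTIVATIONS[kind]()
    except KeyError:
        raise ValueError(f"unknown activation {kind!r}; choose from {sorted(_ACTIVATIONS)}") from None
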