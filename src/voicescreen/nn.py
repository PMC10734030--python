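"""Minimal CPU neural-network layer framework (numpy, NCHW layout).

Every layer implements ``forward(x, train, rng)`` and ``backward(dy)``; the
backward pass consumes the cache left by the most recent forward call and
accumulates parameter gradients in place. Convolutions use im2col with
``sliding_window_view``; batch-norm layers run with fixed statistics (the
frozen-statistics fine-tuning convention), so they act as learnable affine
maps. All computation follows the input dtype, which lets tests run exact
float64 gradient checks against the same code that trains in float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Param:
    """A learnable array with gradient and trainable flag."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, trainable: bool = True, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.trainable = trainable
        self.name = name

    def zero_grad(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def freeze(self) -> None:
        for p in self.params():
            p.trainable = False


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param((rng.standard_normal((n_in, n_out)) * scale).astype(np.float32), name="w")
        self.b = Param(np.zeros(n_out, dtype=np.float32), name="b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Conv2d(Layer):
    """Standard 2-D convolution (groups=1) via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.padding = kernel, stride, padding
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.w = Param((rng.standard_normal((fan_in, c_out)) * scale).astype(np.float32), name="w")
        self.b = Param(np.zeros(c_out, dtype=np.float32), name="b") if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False, rng=None):
        b, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp_shape = x.shape
        view = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        bb, cc, ho, wo = view.shape[:4]
        # (B, Ho, Wo, C, k, k) -> rows of the patch matrix
        cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(bb * ho * wo, cc * k * k)
        self._cols, self._ho, self._wo, self._b = cols, ho, wo, bb
        out = cols @ self.w.value
        if self.b is not None:
            out = out + self.b.value
        return out.reshape(bb, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        k, s, p = self.k, self.stride, self.padding
        b, ho, wo = self._b, self._ho, self._wo
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(b * ho * wo, self.c_out)
        self.w.grad += self._cols.T @ dy_mat
        if self.b is not None:
            self.b.grad += dy_mat.sum(axis=0)
        dcols = (dy_mat @ self.w.value.T).reshape(b, ho, wo, self.c_in, k, k)
        dxp = np.zeros(self._xp_shape, dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class DepthwiseConv2d(Layer):
    """Depthwise (per-channel) convolution, stride 1."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator, padding: int = 0):
        self.channels, self.k, self.padding = channels, kernel, padding
        scale = np.sqrt(2.0 / (kernel * kernel))
        self.w = Param((rng.standard_normal((channels, kernel, kernel)) * scale).astype(np.float32),
                       name="w")
        self.b = Param(np.zeros(channels, dtype=np.float32), name="b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False, rng=None):
        p = self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp = x
        view = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        self._view = view
        out = np.einsum("bchwij,cij->bchw", view, self.w.value, optimize=True)
        return out + self.b.value[None, :, None, None]

    def backward(self, dy):
        p, k = self.padding, self.k
        self.w.grad += np.einsum("bchwij,bchw->cij", self._view, dy, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        _, _, ho, wo = dy.shape
        dxp = np.zeros(self._xp.shape, dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + ho, j:j + wo] += dy * self.w.value[None, :, i, j, None, None]
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    """Normalization with fixed (frozen) statistics plus learnable affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32), name="gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), name="beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False, rng=None):
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        self._xhat = (x - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
        self._inv = inv
        return self.gamma.value[None, :, None, None] * self._xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        self.gamma.grad += (dy * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        return dy * (self.gamma.value * self._inv)[None, :, None, None]


class LayerNormChannels(Layer):
    """Layer norm over the channel axis, for (B, C) or (B, C, H, W) input."""

    def __init__(self, channels: int, eps: float = 1e-6):
        self.gamma = Param(np.ones(channels, dtype=np.float32), name="gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), name="beta")
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def _reshape_affine(self, v, ndim):
        return v[None, :, None, None] if ndim == 4 else v[None, :]

    def forward(self, x, train=False, rng=None):
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        g = self._reshape_affine(self.gamma.value, x.ndim)
        b = self._reshape_affine(self.beta.value, x.ndim)
        return g * self._xhat + b

    def backward(self, dy):
        axes = (0, 2, 3) if dy.ndim == 4 else (0,)
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self._reshape_affine(self.gamma.value, dy.ndim)
        dxhat = dy * g
        m1 = dxhat.mean(axis=1, keepdims=True)
        m2 = (dxhat * self._xhat).mean(axis=1, keepdims=True)
        return self._inv * (dxhat - m1 - self._xhat * m2)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class GELU(Layer):
    """Exact (erf-based) GELU."""

    def forward(self, x, train=False, rng=None):
        self._x = x
        self._phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        return x * self._phi

    def backward(self, dy):
        x = self._x
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        return dy * (self._phi + x * pdf)


class AvgPool2d(Layer):
    """Non-overlapping average pooling (kernel == stride); H, W divisible."""

    def __init__(self, kernel: int):
        self.k = kernel

    def forward(self, x, train=False, rng=None):
        b, c, h, w = x.shape
        k = self.k
        if h % k or w % k:
            raise ValueError(f"AvgPool2d({k}): input {h}x{w} not divisible by kernel")
        self._shape = x.shape
        return x.reshape(b, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, dy):
        k = self.k
        up = np.repeat(np.repeat(dy, k, axis=2), k, axis=3)
        return up / (k * k)


class MaxPool2d(Layer):
    """Max pooling with arbitrary kernel/stride/padding (padding with -inf)."""

    def __init__(self, kernel: int, stride: int, padding: int = 0):
        self.k, self.stride, self.padding = kernel, stride, padding

    def forward(self, x, train=False, rng=None):
        k, s, p = self.k, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        self._xp_shape = x.shape
        view = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        b, c, ho, wo = view.shape[:4]
        flat = view.reshape(b, c, ho, wo, k * k)
        self._arg = flat.argmax(axis=4)
        self._dims = (b, c, ho, wo)
        return flat.max(axis=4)

    def backward(self, dy):
        k, s, p = self.k, self.stride, self.padding
        b, c, ho, wo = self._dims
        dxp = np.zeros(self._xp_shape, dtype=dy.dtype)
        bi, ci, hi, wi = np.indices((b, c, ho, wo), sparse=False)
        rows = hi * s + self._arg // k
        cols = wi * s + self._arg % k
        np.add.at(dxp, (bi, ci, rows, cols), dy)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        b, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / self._hw


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class LayerScale(Layer):
    """Per-channel learnable scaling of an NCHW tensor."""

    def __init__(self, channels: int, init: float = 1e-6):
        self.gamma = Param(np.full(channels, init, dtype=np.float32), name="gamma")

    def params(self):
        return [self.gamma]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x * self.gamma.value[None, :, None, None]

    def backward(self, dy):
        self.gamma.grad += (dy * self._x).sum(axis=(0, 2, 3))
        return dy * self.gamma.value[None, :, None, None]


class Sequential(Layer):
    def __init__(self, layers: list[Layer], name: str = "sequential"):
        self.layers = list(layers)
        self.name = name

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    # -- state helpers -------------------------------------------------------
    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.params()
        if len(params) != len(state):
            raise ValueError("state length mismatch")
        for p, v in zip(params, state):
            if p.value.shape != v.shape:
                raise ValueError("state shape mismatch")
            p.value = v.copy()

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def n_trainable(self) -> int:
        return sum(p.value.size for p in self.params() if p.trainable)

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())


class Adam:
    """Adam optimizer over the trainable parameters of a network."""

    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(p.value.dtype)
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.value = p.value - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad
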