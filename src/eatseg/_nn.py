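"""Minimal numpy neural-network primitives with hand-written backprop.

Self-contained building blocks for small volumetric segmentation networks
trained on CPU: 3×3×3 convolutions (im2col + BLAS matmul), 1×1×1
convolutions, 2× transposed-convolution upsampling, 2× max pooling,
instance normalisation, LeakyReLU, a numerically stable
sigmoid/binary-cross-entropy head, and an RMSProp optimizer.

All tensors are channel-first ``(C, D, H, W)`` float32, single sample
(mini-batch size 1 training). Each layer object caches what its backward
pass needs during ``forward`` and releases it after ``backward``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "Param",
    "Conv3d",
    "Conv1x1",
    "ConvTranspose2x",
    "MaxPool2x",
    "InstanceNorm",
    "LeakyReLU",
    "RMSProp",
    "bce_with_logits",
    "sigmoid",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


@njit(fastmath=True, cache=True)
def _conv3_kernel(xp, w, b, y):  # pragma: no cover - exercised via Conv3d
    """Direct 3³ convolution over a zero-padded input.

    xp: (Ci, D+2, H+2, W+2); y: (Co, D, H, W). One pass per output row with
    the inner x-loop unrolled over the kernel's last axis so it vectorises.
    """
    ci_n = xp.shape[0]
    co_n, d, h, ww = y.shape
    for co in range(co_n):
        for zz in range(d):
            for yy in range(h):
                acc = y[co, zz, yy]
                for xx in range(ww):
                    acc[xx] = b[co]
                for ci in range(ci_n):
                    for kz in range(3):
                        for ky in range(3):
                            src = xp[ci, zz + kz, yy + ky]
                            w0 = w[co, ci, kz, ky, 0]
                            w1 = w[co, ci, kz, ky, 1]
                            w2 = w[co, ci, kz, ky, 2]
                            for xx in range(ww):
                                acc[xx] += w0 * src[xx] + w1 * src[xx + 1] + w2 * src[xx + 2]


@njit(fastmath=True, cache=True)
def _conv3_dw_kernel(xp, dy, dw):  # pragma: no cover - exercised via Conv3d
    """Weight gradient of the 3³ convolution: correlate padded input with dy."""
    ci_n = xp.shape[0]
    co_n, d, h, ww = dy.shape
    for co in range(co_n):
        for ci in range(ci_n):
            for kz in range(3):
                for ky in range(3):
                    a0 = 0.0
                    a1 = 0.0
                    a2 = 0.0
                    for zz in range(d):
                        for yy in range(h):
                            g = dy[co, zz, yy]
                            src = xp[ci, zz + kz, yy + ky]
                            for xx in range(ww):
                                gv = g[xx]
                                a0 += gv * src[xx]
                                a1 += gv * src[xx + 1]
                                a2 += gv * src[xx + 2]
                    dw[co, ci, kz, ky, 0] += a0
                    dw[co, ci, kz, ky, 1] += a1
                    dw[co, ci, kz, ky, 2] += a2


def _pad1(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))


def _conv3_padded(xp: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    y = np.empty((w.shape[0],) + tuple(s - 2 for s in xp.shape[1:]), dtype=xp.dtype)
    _conv3_kernel(xp, w.astype(xp.dtype), b.astype(xp.dtype), y)
    return y


def _conv3_raw(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """3³ convolution, stride 1, pad 1. w: (Co, Ci, 3, 3, 3)."""
    if b is None:
        b = np.zeros(w.shape[0], dtype=x.dtype)
    return _conv3_padded(_pad1(x), w, b)


class Conv3d:
    """3×3×3 convolution with bias (stride 1, padding 1)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Param(_he_init(rng, (cout, cin, 3, 3, 3), fan_in=cin * 27))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._xp = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = _pad1(x)
        self._xp = xp  # padded input reused by both gradient kernels
        return _conv3_padded(xp, self.w.value, self.b.value)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, self._xp = self._xp, None
        if not dy.flags.c_contiguous:
            dy = np.ascontiguousarray(dy)
        dw = np.zeros(self.w.value.shape, dtype=xp.dtype)
        _conv3_dw_kernel(xp, dy, dw)
        self.w.grad += dw
        self.b.grad += dy.sum(axis=(1, 2, 3))
        wf = self.w.value.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        return _conv3_raw(dy, np.ascontiguousarray(wf))


class Conv1x1:
    """1×1×1 convolution (per-voxel linear map across channels)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Param(_he_init(rng, (cout, cin), fan_in=cin))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._x = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = np.tensordot(self.w.value, x, axes=([1], [0]))
        return y + self.b.value[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        self.w.grad += np.tensordot(dy, x, axes=([1, 2, 3], [1, 2, 3]))
        self.b.grad += dy.sum(axis=(1, 2, 3))
        return np.tensordot(self.w.value.T, dy, axes=([1], [0]))


class ConvTranspose2x:
    """2×2×2 transposed convolution, stride 2 (doubles each spatial axis)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Param(_he_init(rng, (cin, cout, 2, 2, 2), fan_in=cin * 8))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._x = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        ci, d, h, w = x.shape
        co = self.w.value.shape[1]
        t = np.tensordot(self.w.value, x, axes=([0], [0]))   # (Co,2,2,2,D,H,W)
        y = t.transpose(0, 4, 1, 5, 2, 6, 3).reshape(co, 2 * d, 2 * h, 2 * w)
        return y + self.b.value[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        co, d2, h2, w2 = dy.shape
        d, h, w = d2 // 2, h2 // 2, w2 // 2
        dyr = dy.reshape(co, d, 2, h, 2, w, 2).transpose(0, 2, 4, 6, 1, 3, 5)
        dyr = np.ascontiguousarray(dyr)                      # (Co,2,2,2,D,H,W)
        self.w.grad += np.tensordot(x, dyr, axes=([1, 2, 3], [4, 5, 6]))
        self.b.grad += dy.sum(axis=(1, 2, 3))
        return np.tensordot(self.w.value, dyr, axes=([1, 2, 3, 4], [0, 1, 2, 3]))


class MaxPool2x:
    """2×2×2 max pooling, stride 2."""

    def __init__(self):
        self._cache = None

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        xr = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        self._cache = None
        c, d, h, w = shape
        out = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
        np.put_along_axis(out, idx[..., None], dy[..., None], axis=-1)
        out = out.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
        out = out.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, d, h, w)
        return out


class InstanceNorm:
    """Per-channel normalisation over the spatial axes, learnable affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.eps = eps
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.value[:, None, None, None] * xhat + self.beta.value[
            :, None, None, None
        ]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += dy.sum(axis=(1, 2, 3))
        dxhat = dy * self.gamma.value[:, None, None, None]
        m1 = dxhat.mean(axis=(1, 2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(1, 2, 3), keepdims=True)
        return (dxhat - m1 - xhat * m2) * inv


class LeakyReLU:
    """max(x, slope·x); the reference blocks use slope 0.1."""

    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._pos = None

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        pos = x > 0
        self._pos = pos
        return np.where(pos, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        pos, self._pos = self._pos, None
        return np.where(pos, dy, self.slope * dy)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-voxel binary cross-entropy summed over class channels.

    Returns ``(loss, dloss/dz)`` where loss is averaged over voxels (not
    over channels) and the target holds independent {0,1} channel labels.
    """
    n_vox = float(np.prod(z.shape[1:]))
    # softplus(z) - z·t, stable form
    loss = np.maximum(z, 0.0) - z * target + np.log1p(np.exp(-np.abs(z)))
    dz = (sigmoid(z) - target) / n_vox
    return float(loss.sum() / n_vox), dz


class RMSProp:
    """Root-mean-square propagation with a fixed learning rate.

    Update: ``v ← α·v + (1−α)·g²``; ``p ← p − lr·g/(√v + eps)``. The
    smoothing constant and epsilon follow common deep-learning framework
    defaults (α = 0.99, eps = 1e−8) and are recorded in run logs.
    """

    def __init__(self, params, lr: float = 1e-4, alpha: float = 0.99, eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.params = list(params)
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            g = p.grad
            v *= self.alpha
            v += (1.0 - self.alpha) * g * g
            p.value -= self.lr * g / (np.sqrt(v) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
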