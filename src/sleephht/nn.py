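"""Minimal seeded neural-network engine on numpy.

Provides exactly the layer set the mixed ANN-CNN classifier needs:
same-padding 3x3 convolution, 2x2 max pooling, flatten, dense layers, and
an Adam optimizer, all with explicit forward/backward passes in float32.
Initialization and batching are driven by a caller-supplied RNG, so runs
are bit-reproducible on a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv2D", "MaxPool2D", "Flatten", "Adam", "sigmoid", "softmax"]

_F = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class Dense:
    """Fully connected layer with He-initialized weights."""

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        self.n_in, self.n_out, self.activation = n_in, n_out, activation
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, (n_in, n_out)).astype(_F)
        self.b = np.zeros(n_out, dtype=_F)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = self._z = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        self._z = z
        if self.activation == "relu":
            return np.maximum(z, 0.0)
        if self.activation == "linear":
            return z
        if self.activation == "sigmoid":
            return sigmoid(z)
        raise ValueError(self.activation)

    def backward(self, da: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dz = da * (self._z > 0)
        elif self.activation == "linear":
            dz = da
        else:  # sigmoid handled at the loss; see models
            raise NotImplementedError
        self.dW[...] = self._x.T @ dz
        self.db[...] = dz.sum(axis=0)
        return dz @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Conv2D:
    """3x3 (configurable) same-padding convolution with ReLU, stride 1.

    Input layout (B, H, W, C_in); weights stored flattened as
    (k*k*C_in, C_out) over an im2col patch matrix.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd for same padding")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = kernel * kernel * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out)).astype(_F)
        self.b = np.zeros(c_out, dtype=_F)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._patches = self._relu_mask = self._in_shape = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # patches gathered by k*k cheap slice copies rather than one
        # strided 6-D copy; column order is (ky, kx, c_in)
        k = self.kernel
        p = k // 2
        b, h, w, c = x.shape
        xp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=_F)
        xp[:, p : p + h, p : p + w, :] = x
        patches = np.empty((b, h, w, k * k, c), dtype=_F)
        i = 0
        for ky in range(k):
            for kx in range(k):
                patches[:, :, :, i, :] = xp[:, ky : ky + h, kx : kx + w, :]
                i += 1
        return patches.reshape(b * h * w, k * k * c)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, _ = x.shape
        self._in_shape = x.shape
        patches = self._im2col(x.astype(_F, copy=False))
        self._patches = patches
        z = patches @ self.W
        z += self.b
        self._relu_mask = z > 0
        return (z * self._relu_mask).reshape(b, h, w, self.c_out)

    def backward(self, da: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        k = self.kernel
        p = k // 2
        dz = da.reshape(b * h * w, self.c_out) * self._relu_mask
        self.dW[...] = self._patches.T @ dz
        self.db[...] = dz.sum(axis=0)
        dpatches = (dz @ self.W.T).reshape(b, h, w, k * k, c)
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=_F)
        i = 0
        for ky in range(k):
            for kx in range(k):
                dxp[:, ky : ky + h, kx : kx + w, :] += dpatches[:, :, :, i, :]
                i += 1
        return dxp[:, p : p + h, p : p + w, :]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MaxPool2D:
    """2x2 max pooling, stride 2. Requires even spatial dimensions."""

    def __init__(self):
        self._idx = self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        self._shape = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = np.ascontiguousarray(xr).reshape(b, h // 2, w // 2, 4, c)
        self._idx = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, da: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        out = np.zeros((b, h // 2, w // 2, 4, c), dtype=_F)
        np.put_along_axis(out, self._idx[:, :, :, None, :], da[:, :, :, None, :], axis=3)
        out = out.reshape(b, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return out.reshape(b, h, w, c)

    def params(self):
        return []


class Flatten:
    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, da: np.ndarray) -> np.ndarray:
        return da.reshape(self._shape)

    def params(self):
        return []


class Adam:
    """Adaptive-moment optimizer over (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
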