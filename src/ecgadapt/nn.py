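"""Minimal CPU neural-network layers with explicit forward/backward passes.

Implements exactly what the page-image classifiers need: 2-D convolution
with SAME padding (output spatial size ceil(in/stride)), batch normalization
with running statistics, ReLU, inverted dropout, a dense layer, the Adam
optimizer, and binary cross-entropy on logits.

Activations are channels-last (B, H, W, C), which keeps the channel axis
contiguous for BLAS. Convolution is computed as a sum of one matmul per
kernel offset (49 for a 7x7 kernel): each offset selects a strided spatial
slice of the padded input and multiplies it by a (C_in, C_out) weight slab.
The same loop structure serves the weight and input gradients, so every
inner operation is a vectorized slice or a GEMM.

All parameters and activations are float32. Every layer exposes ``params``
and ``grads`` as parallel lists of arrays so an optimizer can update them in
place; gradients are verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "BatchNorm2d", "ReLU", "Dropout", "Flatten", "Linear",
    "Sequential", "GradReverse", "Adam", "sigmoid", "bce_with_logits",
    "same_pad", "conv_out_dim",
]


def conv_out_dim(size: int, stride: int) -> int:
    """SAME-padding output size: ceil(size / stride)."""
    return -(-size // stride)


def same_pad(size: int, stride: int, kernel: int) -> tuple[int, int]:
    """(before, after) zero padding for SAME semantics."""
    out = conv_out_dim(size, stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return total // 2, total - total // 2


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """Channels-last convolution, kernel k x k, SAME padding, He-initialized.

    Weights have shape (k, k, C_in, C_out); each kernel offset contributes
    one (C_in, C_out) matmul against a strided slice of the padded input.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        std = np.sqrt(2.0 / (c_in * kernel * kernel))
        w = rng.normal(0.0, std, size=(kernel, kernel, c_in, c_out))
        self.params = [w.astype(np.float32), np.zeros(c_out, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def _pads(self, h: int, w: int):
        ph = same_pad(h, self.stride, self.k)
        pw = same_pad(w, self.stride, self.k)
        return ph, pw

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        k, s = self.k, self.stride
        ph, pw = self._pads(h, w)
        xp = np.pad(x, ((0, 0), ph, pw, (0, 0)))
        ho, wo = conv_out_dim(h, s), conv_out_dim(w, s)
        wt = self.params[0]
        out = np.empty((b, ho, wo, self.c_out), dtype=np.float32)
        out[...] = self.params[1]
        # contiguous per-offset patches are kept for the weight gradient
        patches: list[np.ndarray] = []
        for ki in range(k):
            for kj in range(k):
                p = np.ascontiguousarray(
                    xp[:, ki : ki + ho * s : s, kj : kj + wo * s : s, :])
                out += p.reshape(-1, c).reshape(b, ho, wo, c) @ wt[ki, kj]
                patches.append(p if training else None)
        self._cache = (patches, (b, h, w, c), (ho, wo), (ph, pw))
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        patches, (b, h, w, c), (ho, wo), (ph, pw) = self._cache
        k, s = self.k, self.stride
        wt = self.params[0]
        dmat = dy.reshape(-1, self.c_out)
        self.grads[1][...] = dmat.sum(axis=0)
        dxp = np.zeros((b, h + ph[0] + ph[1], w + pw[0] + pw[1], c),
                       dtype=np.float32)
        dw = self.grads[0]
        for idx, (ki, kj) in enumerate((i, j) for i in range(k) for j in range(k)):
            dw[ki, kj][...] = patches[idx].reshape(-1, c).T @ dmat
            dxp[:, ki : ki + ho * s : s, kj : kj + wo * s : s, :] += \
                dy @ wt[ki, kj].T
        self._cache = None  # free the patch memory
        return dxp[:, ph[0] : ph[0] + h, pw[0] : pw[0] + w, :]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = [np.ones(c, dtype=np.float32), np.zeros(c, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # channels-last: normalize over (batch, height, width) per channel
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, training, x.shape)
        return self.params[0] * xhat + self.params[1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, training, shape = self._cache
        self.grads[0][...] = (dy * xhat).sum(axis=(0, 1, 2))
        self.grads[1][...] = dy.sum(axis=(0, 1, 2))
        g = self.params[0] * inv
        if not training:
            return dy * g
        m = shape[0] * shape[1] * shape[2]
        return g * (dy - self.grads[1] / m - xhat * self.grads[0] / m)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity when p = 0 or in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout p must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) \
            / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(1.0 / f_in)
        w = rng.normal(0.0, std, size=(f_in, f_out))
        self.params = [w.astype(np.float32), np.zeros(f_out, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.params[0].T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:  # type: ignore[override]
        return [p for layer in self.layers for p in layer.params]

    @params.setter
    def params(self, value) -> None:  # Layer.__init__ compatibility
        if value:
            raise AttributeError("Sequential params are owned by its layers")

    @property
    def grads(self) -> list[np.ndarray]:  # type: ignore[override]
        return [g for layer in self.layers for g in layer.grads]

    @grads.setter
    def grads(self, value) -> None:
        if value:
            raise AttributeError("Sequential grads are owned by its layers")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class GradReverse(Layer):
    """Gradient reversal: identity forward, -lam * g backward.

    The scaling coefficient ``lam`` is set per step (the adaptive schedule)
    before backpropagating the domain loss.
    """

    def __init__(self, lam: float = 1.0):
        super().__init__()
        if lam < 0:
            raise ValueError("lam must be >= 0")
        self.lam = float(lam)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return -self.lam * dy


def grad_reverse(x: np.ndarray, lam: float) -> tuple[np.ndarray, GradReverse]:
    """Functional form: returns (x unchanged, layer whose backward applies
    the -lam scaling)."""
    layer = GradReverse(lam)
    return layer.forward(x), layer


class Adam:
    """Adam optimizer updating a fixed list of parameter arrays in place."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z = logits.astype(np.float64).ravel()
    y = targets.astype(np.float64).ravel()
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad.reshape(logits.shape).astype(np.float32)
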