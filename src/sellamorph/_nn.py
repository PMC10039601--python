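"""Minimal CPU conv-net engine for the segmentation U-net.

Implements exactly the layers the classic U-net needs — 3x3 'same'
convolution, ReLU, 2x2 max-pooling, 2x2-stride-2 transposed convolution,
channel concatenation and a 1x1 output head — with explicit forward and
backward passes (im2col + BLAS matmuls), a numerically stable
binary-cross-entropy-with-logits loss, and an RMSprop optimizer.

All activations are ``float32`` arrays in channels-last ``(N, H, W, C)``
layout, chosen so that im2col and the matmul reshapes are contiguous
copies (the engine is memory-bound on CPU).  Everything here is
deterministic given the seed used to initialize parameters.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, 9*C) patches of the zero-padded input."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((n, h, w, 9 * c), dtype=x.dtype)
    k = 0
    for dy in range(3):
        for dx in range(3):
            cols[:, :, :, k * c : (k + 1) * c] = xp[:, dy : dy + h, dx : dx + w, :]
            k += 1
    return cols.reshape(n * h * w, 9 * c)


def _col2im3(dcols: np.ndarray, n: int, h: int, w: int, c: int) -> np.ndarray:
    """Adjoint of :func:`_im2col3` (scatter-add back to image layout)."""
    dcols = dcols.reshape(n, h, w, 9 * c)
    dxp = np.zeros((n, h + 2, w + 2, c), dtype=dcols.dtype)
    k = 0
    for dy in range(3):
        for dx in range(3):
            dxp[:, dy : dy + h, dx : dx + w, :] += dcols[:, :, :, k * c : (k + 1) * c]
            k += 1
    return dxp[:, 1 : h + 1, 1 : w + 1, :]


class Layer:
    """A layer with (possibly empty) parallel ``params``/``grads`` lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []


class Conv3x3(Layer):
    """3x3 convolution, zero padding, unit stride, with bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        std = np.sqrt(2.0 / (c_in * 9))
        self.weight = rng.normal(0.0, std, size=(9 * c_in, c_out)).astype(F32)
        self.bias = np.zeros(c_out, dtype=F32)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]
        self.c_in = c_in
        self.c_out = c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        cols = _im2col3(x)
        self._cache = (cols, (n, h, w, c))
        return (cols @ self.weight + self.bias).reshape(n, h, w, self.c_out)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, (n, h, w, c) = self._cache
        g2 = gy.reshape(n * h * w, self.c_out)
        self.grads[0] += cols.T @ g2
        self.grads[1] += g2.sum(axis=0)
        return _col2im3(g2 @ self.weight.T, n, h, w, c)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; input sides must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = (n, h, w, c)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        g = np.zeros((n, h // 2, w // 2, c, 4), dtype=gy.dtype)
        np.put_along_axis(g, self._idx[..., None], gy[..., None], axis=-1)
        g = g.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return g.reshape(n, h, w, c)


class UpConv2(Layer):
    """2x2 transposed convolution with stride 2 (resolution doubling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        std = np.sqrt(2.0 / c_in)
        self.weight = rng.normal(0.0, std, size=(c_in, 4 * c_out)).astype(F32)
        self.bias = np.zeros(c_out, dtype=F32)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]
        self.c_in = c_in
        self.c_out = c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        flat = x.reshape(n * h * w, c)
        self._cache = (flat, (n, h, w, c))
        y = (flat @ self.weight).reshape(n, h, w, 2, 2, self.c_out)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, self.c_out)
        return y + self.bias

    def backward(self, gy: np.ndarray) -> np.ndarray:
        flat, (n, h, w, c) = self._cache
        self.grads[1] += gy.sum(axis=(0, 1, 2))
        g = gy.reshape(n, h, 2, w, 2, self.c_out).transpose(0, 1, 3, 2, 4, 5)
        g = g.reshape(n * h * w, 4 * self.c_out)
        self.grads[0] += flat.T @ g
        return (g @ self.weight.T).reshape(n, h, w, c)


class Conv1x1(Layer):
    """1x1 convolution head mapping features to per-pixel logits."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        std = np.sqrt(1.0 / c_in)
        self.weight = rng.normal(0.0, std, size=(c_in, c_out)).astype(F32)
        self.bias = np.zeros(c_out, dtype=F32)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]
        self.c_out = c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        flat = x.reshape(n * h * w, c)
        self._cache = (flat, (n, h, w, c))
        return (flat @ self.weight + self.bias).reshape(n, h, w, self.c_out)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        flat, (n, h, w, c) = self._cache
        g = gy.reshape(n * h * w, self.c_out)
        self.grads[0] += flat.T @ g
        self.grads[1] += g.sum(axis=0)
        return (g @ self.weight.T).reshape(n, h, w, c)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross entropy on logits; returns (loss, dL/dlogits)."""
    z = logits.astype(np.float64)
    loss = np.maximum(z, 0) - z * targets + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(logits) - targets.astype(F32)) / logits.size
    return float(loss.mean()), grad.astype(F32)


class RMSprop:
    """RMSprop with the conventional smoothing constant alpha=0.99."""

    def __init__(self, layers: list[Layer], lr: float, alpha: float = 0.99,
                 eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.sq = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.grads:
                g[...] = 0

    def step(self) -> None:
        for layer, sqs in zip(self.layers, self.sq):
            for p, g, v in zip(layer.params, layer.grads, sqs):
                v *= self.alpha
                v += (1.0 - self.alpha) * g * g
                p -= self.lr * g / (np.sqrt(v) + self.eps)
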