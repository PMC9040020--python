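"""Minimal feed-forward / convolutional network layers with reverse-mode gradients.

Everything operates on float32 numpy arrays shaped (batch, length, channels)
for sequence layers and (batch, features) for dense layers.  Each layer
caches what its backward pass needs; ``backward`` must be called with the
gradient of the loss w.r.t. the layer output immediately after the
corresponding ``forward``.

Parameters carry a ``trainable`` flag; the Adam optimizer skips frozen
parameters, which is how the two-stage training freezes whole feature
modules.
"""

from __future__ import annotations

import hashlib
from typing import Sequence

import numpy as np


class Parameter:
    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, name: str = "", trainable: bool = True):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def params_digest(params: Sequence[Parameter]) -> str:
    """SHA-256 over the concatenated raw bytes of the parameter values."""
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv1D(Layer):
    """1-D convolution (cross-correlation), stride 1, 'same' zero padding.

    Weight shape (kernel_len, in_channels, out_channels).  With
    ``padding='valid'`` the output length is L - kernel_len + 1.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_len: int,
                 rng: np.random.Generator, padding: str = "same", name: str = "conv"):
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_len = kernel_len
        self.padding = padding
        fan_in = kernel_len * in_channels
        self.w = Parameter(
            _glorot(rng, fan_in, out_channels, (kernel_len, in_channels, out_channels)),
            name=f"{name}.w",
        )
        self.b = Parameter(np.zeros(out_channels, dtype=np.float32), name=f"{name}.b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def _pad_amounts(self) -> tuple[int, int]:
        if self.padding == "valid":
            return 0, 0
        total = self.kernel_len - 1
        left = total // 2
        return left, total - left

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        batch, length, _ = x.shape
        left, right = self._pad_amounts()
        xp = np.pad(x, ((0, 0), (left, right), (0, 0))) if (left or right) else x
        k, cin, cout = self.kernel_len, self.in_channels, self.out_channels
        out_len = xp.shape[1] - k + 1
        # im2col: (batch, out_len, k*cin)
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B, out_len, cin, k)
        cols = win.transpose(0, 1, 3, 2).reshape(batch, out_len, k * cin)
        wmat = self.w.value.reshape(k * cin, cout)
        y = cols @ wmat + self.b.value
        self._cache = (cols, x.shape, left)
        return y

    def backward(self, grad_out):
        cols, x_shape, left = self._cache
        batch, length, cin = x_shape
        k, cout = self.kernel_len, self.out_channels
        out_len = grad_out.shape[1]
        g2 = grad_out.reshape(-1, cout)
        self.w.grad += (cols.reshape(-1, k * cin).T @ g2).reshape(self.w.value.shape)
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.w.value.reshape(k * cin, cout).T).reshape(
            batch, out_len, k, cin
        )
        pad_len = length + (k - 1 if self.padding == "same" else 0)
        dxp = np.zeros((batch, pad_len, cin), dtype=np.float32)
        for m in range(k):
            dxp[:, m:m + out_len, :] += dcols[:, :, m, :]
        return dxp[:, left:left + length, :]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad_out):
        return np.where(self._mask, grad_out, 0.0).astype(np.float32)


class MaxPool1D(Layer):
    """Non-overlapping max pooling; trailing positions that do not fill a
    window are dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, train=False):
        batch, length, ch = x.shape
        n_out = length // self.pool
        xt = x[:, : n_out * self.pool, :].reshape(batch, n_out, self.pool, ch)
        self._argmax = xt.argmax(axis=2)
        self._in_shape = x.shape
        return xt.max(axis=2)

    def backward(self, grad_out):
        batch, n_out, ch = grad_out.shape
        dxt = np.zeros((batch, n_out, self.pool, ch), dtype=np.float32)
        b_idx, o_idx, c_idx = np.ogrid[:batch, :n_out, :ch]
        dxt[b_idx, o_idx, self._argmax, c_idx] = grad_out
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, : n_out * self.pool, :] = dxt.reshape(batch, n_out * self.pool, ch)
        return dx


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, name: str = "dense"):
        self.w = Parameter(
            _glorot(rng, in_features, out_features, (in_features, out_features)),
            name=f"{name}.w",
        )
        self.b = Parameter(np.zeros(out_features, dtype=np.float32), name=f"{name}.b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad_out):
        self.w.grad += self._x.T @ grad_out
        self.b.grad += grad_out.sum(axis=0)
        return grad_out @ self.w.value.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad_out):
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, length) for 3-D inputs."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=np.float32), name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, axes, x.shape, train)
        return (self.gamma.value * xhat + self.beta.value).astype(np.float32)

    def backward(self, grad_out):
        xhat, inv_std, axes, shape, train = self._cache
        self.gamma.grad += (grad_out * xhat).sum(axis=axes)
        self.beta.grad += grad_out.sum(axis=axes)
        g = grad_out * self.gamma.value
        if not train:
            return (g * inv_std).astype(np.float32)
        n = np.prod([shape[a] for a in axes])
        dxhat = g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv_std
        return dx.astype(np.float32)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


def softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stabilized softmax along the last axis."""
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and gradient w.r.t. logits.

    ``labels`` are integer class indices.
    """
    probs = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred.astype(np.float64) - target.astype(np.float64)
    loss = float(np.mean(diff ** 2))
    grad = (2.0 * diff / diff.size).astype(np.float32)
    return loss, grad


class Adam:
    """Adam with decoupled weight decay (the AdamW variant when
    ``weight_decay`` > 0); decay is not applied to biases or batch-norm
    parameters (1-D values)."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if not p.trainable:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay > 0.0 and p.value.ndim > 1:
                p.value -= self.lr * self.weight_decay * p.value

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out
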