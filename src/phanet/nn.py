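"""Minimal NumPy neural-network engine.

Layers are stateless with respect to activations: ``forward`` returns
``(output, cache)`` and ``backward(cache, grad_out)`` returns the input
gradient while accumulating parameter gradients into each :class:`Param`.
This lets a single layer (shared weights) be applied to several inputs in
one step — each application keeps its own cache, and gradients from all
applications sum into the same parameters, which is exactly the semantics
weight sharing requires.

All computation is float32; convolutions are 'valid' (no padding), stride 1,
expressed as a sum of k channel-mixing matmuls so BLAS does the heavy
lifting.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

import numpy as np


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray):  # -> (y, cache)
        raise NotImplementedError

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution over (batch, channels, length), valid padding, stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        self.k = kernel_size
        fan_in = in_channels * kernel_size
        bound = 1.0 / np.sqrt(fan_in)
        self.W = Param(rng.uniform(-bound, bound, size=(out_channels, in_channels, kernel_size)))
        self.b = Param(rng.uniform(-bound, bound, size=(out_channels,)))

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray):
        B, C, L = x.shape
        Lout = L - self.k + 1
        if Lout < 1:
            raise ValueError(
                f"input length {L} shorter than kernel size {self.k}")
        y = np.empty((B, self.W.value.shape[0], Lout), dtype=np.float32)
        y[...] = self.b.value[None, :, None]
        for j in range(self.k):
            # (Cout, Cin) @ (B, Cin, Lout) -> (B, Cout, Lout)
            y += np.matmul(self.W.value[:, :, j], x[:, :, j:j + Lout])
        return y, x

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        x = cache
        B, C, L = x.shape
        Lout = dy.shape[2]
        dx = np.zeros_like(x)
        for j in range(self.k):
            xj = x[:, :, j:j + Lout]
            self.W.grad[:, :, j] += np.tensordot(dy, xj, axes=([0, 2], [0, 2]))
            dx[:, :, j:j + Lout] += np.matmul(self.W.value[:, :, j].T, dy)
        self.b.grad += dy.sum(axis=(0, 2))
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray):
        y = np.maximum(x, 0.0)
        return y, (x > 0.0)

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        return dy * cache


class MaxPool1d(Layer):
    """Local max pooling with stride == window; trailing remainder is dropped.

    If the (truncated) length is shorter than the window, the layer degrades
    to a single max over what remains, so short inputs still pass through.
    """

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x: np.ndarray):
        B, C, L = x.shape
        p = min(self.pool, L)
        n = L // p
        xt = x[:, :, : n * p].reshape(B, C, n, p)
        idx = xt.argmax(axis=3)
        y = np.take_along_axis(xt, idx[..., None], axis=3)[..., 0]
        return y, (x.shape, p, n, idx)

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        shape, p, n, idx = cache
        dx = np.zeros(shape, dtype=np.float32)
        dxt = dx[:, :, : n * p].reshape(shape[0], shape[1], n, p)
        np.put_along_axis(dxt, idx[..., None], dy[..., None], axis=3)
        return dx


class GlobalMaxPool(Layer):
    """Max over the position axis: (B, C, L) -> (B, C)."""

    def forward(self, x: np.ndarray):
        idx = x.argmax(axis=2)
        y = np.take_along_axis(x, idx[..., None], axis=2)[..., 0]
        return y, (x.shape, idx)

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        shape, idx = cache
        dx = np.zeros(shape, dtype=np.float32)
        np.put_along_axis(dx, idx[..., None], dy[..., None], axis=2)
        return dx


class GlobalMeanPool(Layer):
    """Mean over the position axis: (B, C, L) -> (B, C)."""

    def forward(self, x: np.ndarray):
        return x.mean(axis=2), x.shape

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        shape = cache
        return np.broadcast_to(dy[..., None] / shape[2], shape).astype(np.float32)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_features)
        self.W = Param(rng.uniform(-bound, bound, size=(out_features, in_features)))
        self.b = Param(rng.uniform(-bound, bound, size=(out_features,)))

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray):
        return x @ self.W.value.T + self.b.value, x

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        x = cache
        self.W.grad += dy.T @ x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> List[Param]:
        out: List[Param] = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x: np.ndarray):
        caches = []
        for lay in self.layers:
            x, c = lay.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, caches, dy: np.ndarray) -> np.ndarray:
        for lay, c in zip(reversed(self.layers), reversed(caches)):
            dy = lay.backward(c, dy)
        return dy


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, dloss/dlogits).

    Uses the log-sum-exp form ``max(z,0) - z*t + log(1+exp(-|z|))`` for
    numerical stability.
    """
    z = logits.astype(np.float64)
    t = targets.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - t) / z.size).astype(np.float32)
    return loss, grad


class Adam:
    """Adaptive-moment first-order optimizer over a set of unique Params."""

    def __init__(self, params: Iterable[Param], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        # deduplicate by identity so shared parameters get one state/update
        seen, unique = set(), []
        for p in params:
            if id(p) not in seen:
                seen.add(id(p))
                unique.append(p)
        self.params = unique
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * np.square(p.grad)
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def unique_params(params: Iterable[Param]) -> List[Param]:
    seen, out = set(), []
    for p in params:
        if id(p) not in seen:
            seen.add(id(p))
            out.append(p)
    return out
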