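"""Minimal NumPy layers with explicit backpropagation.

Only what the loop classifier needs: stride-1 same-padding convolution
(im2col via ``sliding_window_view``), batch normalization (2d and 1d),
ReLU, inverted dropout, global average pooling, dense layers, a fused
sigmoid + binary-cross-entropy head, and Adam. Everything runs in float32;
all randomness flows through explicitly passed ``numpy.random.Generator``
objects, so a fixed seed gives bitwise-reproducible training on one device.

Each layer exposes ``params``/``grads`` dicts (aligned keys) plus
``forward(x, train, rng)`` and ``backward(dout)``; ``backward`` must be
called directly after the corresponding training-mode forward.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d", "BatchNorm2d", "BatchNorm1d", "ReLU", "Dropout",
    "GlobalAvgPool", "Dense", "Adam",
    "sigmoid", "bce_with_logits", "bce_with_logits_grad",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> float:
    """Mean BCE computed from logits: softplus(z) - y*z (numerically stable)."""
    z = z.astype(np.float64)
    softplus = np.where(z > 0, z + np.log1p(np.exp(-np.abs(z))), np.log1p(np.exp(z)))
    return float(np.mean(softplus - y * z))


def bce_with_logits_grad(z: np.ndarray, y: np.ndarray) -> np.ndarray:
    return (sigmoid(z) - y) / len(y)


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, He-normal init.

    Operates channels-last: input (N, H, W, cin) -> output (N, Ho, Wo, cout)
    with ``Ho = H + 2*pad - k + 1``, as a single im2col GEMM per call.
    ``pad=None`` means same padding ((k-1)/2); ``pad=0`` is a valid
    (unpadded) convolution. The canonical parameter layout is
    (cout, cin*k*k) with (cin, ki, kj) inner ordering."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 pad: int | None = None):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = (k - 1) // 2 if pad is None else int(pad)
        fan_in = cin * k * k
        self.params["W"] = (rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self._cols = None

    def out_size(self, h: int) -> int:
        return h + 2 * self.pad - self.k + 1

    def _w_gemm(self) -> np.ndarray:
        # (k*k*cin, cout) with (ki, kj, cin) inner ordering, matching im2col
        k, c, f = self.k, self.cin, self.cout
        return np.ascontiguousarray(
            self.params["W"].reshape(f, c, k, k).transpose(2, 3, 1, 0).reshape(k * k * c, f)
        )

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        N, H, W, C = x.shape
        p, k = self.pad, self.k
        if p:
            xp = np.zeros((N, H + 2 * p, W + 2 * p, C), dtype=np.float32)
            xp[:, p : p + H, p : p + W, :] = x
        else:
            xp = x
        v = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,Ho,Wo,C,k,k
        return np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3)).reshape(-1, k * k * C)

    def forward(self, x, train=False, rng=None):
        N, H, W, C = x.shape
        ho, wo = self.out_size(H), self.out_size(W)
        if ho < 1 or wo < 1:
            raise ValueError(f"kernel {self.k} too large for {H}x{W} input with pad {self.pad}")
        cols = self._im2col(x)
        out = (cols @ self._w_gemm() + self.params["b"]).reshape(N, ho, wo, self.cout)
        if train:
            self._cols, self._shape = cols, (N, H, W, C)
        return out

    def backward(self, dout):
        N, H, W, C = self._shape
        p, k = self.pad, self.k
        ho, wo = self.out_size(H), self.out_size(W)
        dmat = dout.reshape(-1, self.cout)
        dw = self._cols.T @ dmat  # (k*k*cin, cout)
        self.grads["W"] = np.ascontiguousarray(
            dw.reshape(k, k, C, self.cout).transpose(3, 2, 0, 1).reshape(self.cout, -1)
        )
        self.grads["b"] = dmat.sum(axis=0).astype(np.float32)
        dcols = (dmat @ self._w_gemm().T).reshape(N, ho, wo, k, k, C)
        dxp = np.zeros((N, H + 2 * p, W + 2 * p, C), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, di : di + ho, dj : dj + wo, :] += dcols[:, :, :, di, dj, :]
        self._cols = None
        return dxp[:, p : p + H, p : p + W, :] if p else dxp


class _BatchNorm(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.c, self.momentum, self.eps = c, momentum, eps
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)

    axes: tuple
    shape: tuple

    def forward(self, x, train=False, rng=None):
        if not train:
            # fused affine in float32: gamma/sqrt(var+eps) * x + shifted beta
            istd = 1.0 / np.sqrt(self.running_var + self.eps)
            scale = (self.params["gamma"] * istd).astype(np.float32)
            shift = (self.params["beta"] - self.params["gamma"] * self.running_mean * istd).astype(np.float32)
            return x * scale.reshape(self.shape) + shift.reshape(self.shape)
        mu = x.mean(axis=self.axes)
        var = x.var(axis=self.axes)
        self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
        self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = ((x - mu.reshape(self.shape)) * istd.reshape(self.shape)).astype(np.float32)
        self._xhat, self._istd = xhat, istd
        return (self.params["gamma"].reshape(self.shape) * xhat
                + self.params["beta"].reshape(self.shape)).astype(np.float32)

    def backward(self, dout):
        xhat, istd = self._xhat, self._istd
        m = dout.size // self.c
        self.grads["gamma"] = (dout * xhat).sum(axis=self.axes).astype(np.float32)
        self.grads["beta"] = dout.sum(axis=self.axes).astype(np.float32)
        dxhat = dout * self.params["gamma"].reshape(self.shape)
        s1 = dxhat.sum(axis=self.axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=self.axes, keepdims=True)
        dx = (istd.reshape(self.shape) / m) * (m * dxhat - s1 - xhat * s2)
        self._xhat = None
        return dx.astype(np.float32)


class BatchNorm2d(_BatchNorm):
    """Per-channel batch norm on channels-last (N, H, W, C) maps."""

    axes = (0, 1, 2)

    def __init__(self, c, **kw):
        super().__init__(c, **kw)
        self.shape = (1, 1, 1, c)


class BatchNorm1d(_BatchNorm):
    axes = (0,)

    def __init__(self, c, **kw):
        super().__init__(c, **kw)
        self.shape = (1, c)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, p: float):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0:
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(np.float32)

    def backward(self, dout):
        if self.p == 0:
            return dout
        return dout * self._mask


class GlobalAvgPool(Layer):
    """(N, H, W, C) -> (N, C) spatial mean."""

    def forward(self, x, train=False, rng=None):
        if train:
            self._hw = x.shape[1:3]
        return x.mean(axis=(1, 2), dtype=np.float32)

    def backward(self, dout):
        H, W = self._hw
        N, C = dout.shape
        return np.broadcast_to(
            (dout / (H * W))[:, None, None, :], (N, H, W, C)
        ).astype(np.float32)


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = (rng.standard_normal((cin, cout)) * np.sqrt(2.0 / cin)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x, train=False, rng=None):
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = (self._x.T @ dout).astype(np.float32)
        self.grads["b"] = dout.sum(axis=0).astype(np.float32)
        self._x = None
        return (dout @ self.params["W"].T).astype(np.float32)


class Adam:
    """Adam with bias correction; operates in place on the layers' params."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[li][k] = self.b1 * self.m[li][k] + (1 - self.b1) * g
                self.v[li][k] = self.b2 * self.v[li][k] + (1 - self.b2) * g * g
                mhat = self.m[li][k] / c1
                vhat = self.v[li][k] / c2
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
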