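"""Layer primitives with explicit forward/backward passes.

All activations use the ``(batch, channels, height, width)`` layout.
Each layer instance caches whatever its backward pass needs during
``forward``; a layer therefore appears at most once in a network graph.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: parameters, gradients and a trainable flag."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.trainable: bool = True

    def init_params(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def forward(self, *xs: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with square kernel.

    Implemented as im2col + matmul; the backward pass scatters column
    gradients back with a small loop over the kernel footprint.
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3,
                 stride: int = 1, pad: int | None = None, bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride = ksize, stride
        self.pad = (ksize - 1) // 2 if pad is None else pad
        self.use_bias = bias
        self.params["W"] = np.zeros((out_ch, in_ch, ksize, ksize))
        if bias:
            self.params["b"] = np.zeros(out_ch)
        self.zero_grad()

    def init_params(self, rng: np.random.Generator) -> None:
        fan_in = self.in_ch * self.k * self.k
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      size=self.params["W"].shape)
        if self.use_bias:
            self.params["b"] = np.zeros(self.out_ch)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        p, s, k = self.pad, self.stride, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        bo, _, ho, wo, _, _ = cols.shape
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)
                                     ).reshape(bo * ho * wo, c * k * k)
        wmat = self.params["W"].reshape(self.out_ch, c * k * k)
        y = cols2 @ wmat.T
        if self.use_bias:
            y += self.params["b"]
        y = y.reshape(bo, ho, wo, self.out_ch).transpose(0, 3, 1, 2)
        self._cache = (x.shape, xp.shape, cols2, ho, wo)
        return y

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        (xshape, xpshape, cols2, ho, wo) = self._cache
        b, c, h, w = xshape
        p, s, k = self.pad, self.stride, self.k
        gy2 = gy.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        wmat = self.params["W"].reshape(self.out_ch, c * k * k)
        self.grads["W"] += (gy2.T @ cols2).reshape(self.params["W"].shape)
        if self.use_bias:
            self.grads["b"] += gy2.sum(axis=0)
        gcols = (gy2 @ wmat).reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros(xpshape)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += gcols[..., i, j]
        gx = gxp[:, :, p:p + h, p:p + w] if p else gxp
        return (gx,)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        return (gy * self._mask,)


class MaxPool2d(Layer):
    """Non-overlapping max pooling (window = stride); input sizes must divide."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        n = self.size
        if h % n or w % n:
            raise ValueError(f"spatial size ({h},{w}) not divisible by {n}")
        xr = (x.reshape(b, c, h // n, n, w // n, n)
              .transpose(0, 1, 2, 4, 3, 5)
              .reshape(b, c, h // n, w // n, n * n))
        self._argmax = xr.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        b, c, h, w = self._xshape
        n = self.size
        gxr = np.zeros((b, c, h // n, w // n, n * n))
        np.put_along_axis(gxr, self._argmax[..., None], gy[..., None], axis=-1)
        gx = (gxr.reshape(b, c, h // n, w // n, n, n)
              .transpose(0, 1, 2, 4, 3, 5)
              .reshape(b, c, h, w))
        return (gx,)


class GlobalAvgPool(Layer):
    """Spatial mean per channel: (B, C, H, W) -> (B, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[2] == 0 or x.shape[3] == 0:
            raise ValueError("GlobalAvgPool expects a non-empty B,C,H,W array")
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        b, c, h, w = self._xshape
        gx = np.broadcast_to(gy[:, :, None, None], (b, c, h, w)) / (h * w)
        return (gx.copy(),)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.use_bias = bias
        self.params["W"] = np.zeros((out_dim, in_dim))
        if bias:
            self.params["b"] = np.zeros(out_dim)
        self.zero_grad()

    def init_params(self, rng: np.random.Generator) -> None:
        self.params["W"] = rng.normal(0.0, np.sqrt(1.0 / self.in_dim),
                                      size=(self.out_dim, self.in_dim))
        if self.use_bias:
            self.params["b"] = np.zeros(self.out_dim)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.params["W"].T
        if self.use_bias:
            y = y + self.params["b"]
        return y

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        self.grads["W"] += gy.T @ self._x
        if self.use_bias:
            self.grads["b"] += gy.sum(axis=0)
        return (gy @ self.params["W"],)


class Add(Layer):
    """Element-wise sum of two activations (residual connection)."""

    def forward(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        if a.shape != b.shape:
            raise ValueError(f"Add shape mismatch: {a.shape} vs {b.shape}")
        return a + b

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        return (gy, gy)
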