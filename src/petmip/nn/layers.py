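"""Dense / convolutional layers with explicit backward passes (float32, NCHW)."""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T

    @property
    def n_params(self) -> int:
        return self.w.value.size + self.b.value.size


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N*oh*ow, C*k*k) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, oh, ow, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(xp.shape[0] * oh * ow, -1)
    return np.ascontiguousarray(cols)


class Conv2d(Layer):
    """3x3-style convolution via im2col + GEMM; He-initialized."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        k: int = 3,
        stride: int = 1,
        pad: int = 1,
    ):
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in * k * k)))
        self.b = Param(np.zeros(c_out))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        self._cols = _im2col(xp, k, s, oh, ow)
        self._shape = (n, c, h, w, oh, ow)
        out = self._cols @ self.w.value.T + self.b.value
        return out.reshape(n, oh, ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w, oh, ow = self._shape
        p, k, s = self.pad, self.k, self.stride
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.w.grad += dflat.T @ self._cols
        self.b.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.w.value).reshape(n, oh, ow, c, k, k).transpose(
            0, 3, 1, 2, 4, 5
        )
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / (h * w), self._shape
        ).astype(np.float32)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
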