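"""Standard 1D network layers: convolution, batch-norm, pooling, dense."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Layer, Parameter, glorot_uniform

__all__ = ["Conv1d", "BatchNorm1d", "MaxPool1d", "ReLU", "Flatten", "Dense"]


def _windows(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """Strided view of shape (B, O, C, kernel) over the length axis."""
    win = sliding_window_view(x, kernel, axis=1)  # (B, W-k+1, C, k)
    return win[:, ::stride]


class Conv1d(Layer):
    """1D convolution (cross-correlation) over (batch, length, channels).

    ``padding='same'`` (stride 1 only) keeps the output length equal to the
    input length; ``'valid'`` uses no padding and the output length is
    ``floor((w - kernel)/stride) + 1``.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: str = "valid",
                 rng: np.random.Generator | None = None, name: str = "conv"):
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding mode {padding!r}")
        if padding == "same" and stride != 1:
            raise ValueError("'same' padding requires stride 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        rng = rng if rng is not None else np.random.default_rng(0)
        w = glorot_uniform(rng, (kernel, in_channels, out_channels),
                           fan_in=kernel * in_channels, fan_out=kernel * out_channels)
        self.weight = Parameter(f"{name}.weight", w)
        self.bias = Parameter(f"{name}.bias", np.zeros(out_channels))
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def _pad_amounts(self) -> tuple[int, int]:
        if self.padding == "same":
            left = (self.kernel - 1) // 2
            return left, self.kernel - 1 - left
        return 0, 0

    def output_length(self, w: int) -> int:
        if self.padding == "same":
            return w
        o = (w - self.kernel) // self.stride + 1
        if o < 1:
            raise ValueError(f"input length {w} too short for kernel {self.kernel}")
        return o

    def _tap_slice(self, j: int, o: int) -> slice:
        # input positions j + stride*t for t = 0..o-1
        return slice(j, j + self.stride * (o - 1) + 1, self.stride)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        left, right = self._pad_amounts()
        xp = np.pad(x, ((0, 0), (left, right), (0, 0))) if (left or right) else x
        b = x.shape[0]
        o = (xp.shape[1] - self.kernel) // self.stride + 1
        # im2col: one contiguous copy, then a single GEMM
        win = _windows(xp, self.kernel, self.stride)        # (B, O, C, k) view
        col = win.reshape(b * o, self.in_channels * self.kernel)
        wmat = self.weight.value.transpose(1, 0, 2).reshape(
            self.in_channels * self.kernel, self.out_channels)
        out = (col @ wmat).reshape(b, o, self.out_channels)
        out += self.bias.value
        self._cache = (col, x.shape, xp.shape, left, o)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        col, x_shape, xp_shape, left, o = self._cache
        b = dout.shape[0]
        self.bias.grad += dout.sum(axis=(0, 1))
        dout2 = dout.reshape(b * o, self.out_channels)
        dwmat = col.T @ dout2                               # (C*k, F)
        self.weight.grad += dwmat.reshape(
            self.in_channels, self.kernel, self.out_channels).transpose(1, 0, 2)
        dcol = (dout2 @ self.weight.value.transpose(1, 0, 2).reshape(
            self.in_channels * self.kernel, self.out_channels).T)
        dcol = dcol.reshape(b, o, self.in_channels, self.kernel)
        dxp = np.zeros(xp_shape)
        for j in range(self.kernel):  # col2im scatter, one tap at a time
            dxp[:, self._tap_slice(j, o), :] += dcol[:, :, :, j]
        if left or xp_shape[1] != x_shape[1]:
            dxp = dxp[:, left:left + x_shape[1], :]
        return dxp


class MaxPool1d(Layer):
    """Windowed channelwise maximum. Output length floor((w - pool)/stride) + 1."""

    def __init__(self, pool: int, stride: int | None = None):
        self.pool = pool
        self.stride = stride if stride is not None else pool
        self._cache = None

    def output_length(self, w: int) -> int:
        if self.pool > w:
            raise ValueError(f"pool window {self.pool} exceeds input length {w}")
        return (w - self.pool) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.output_length(x.shape[1])
        win = _windows(x, self.pool, self.stride)  # (B, O, C, p)
        amax = win.argmax(axis=-1)
        out = np.take_along_axis(win, amax[..., None], axis=-1)[..., 0]
        self._cache = (amax, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        amax, x_shape = self._cache
        b, o, c = dout.shape
        dx = np.zeros(x_shape)
        pos = np.arange(o)[None, :, None] * self.stride + amax  # (B, O, C)
        bidx = np.arange(b)[:, None, None]
        cidx = np.arange(c)[None, None, :]
        np.add.at(dx, (bidx, pos, cidx), dout)
        return dx


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length).

    Uses batch statistics in training and exponentially-averaged running
    statistics at inference, so an evaluated network is a pure function.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def buffers(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 1))
        self.beta.grad += dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma.value
        if not train:
            return dxhat * inv_std
        n = dout.shape[0] * dout.shape[1]
        return (inv_std / n) * (n * dxhat
                                - dxhat.sum(axis=(0, 1))
                                - xhat * (dxhat * xhat).sum(axis=(0, 1)))


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, name: str = "dense"):
        rng = rng if rng is not None else np.random.default_rng(0)
        w = glorot_uniform(rng, (in_features, out_features),
                           fan_in=in_features, fan_out=out_features)
        self.weight = Parameter(f"{name}.weight", w)
        self.bias = Parameter(f"{name}.bias", np.zeros(out_features))
        self._x = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dout
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value.T
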