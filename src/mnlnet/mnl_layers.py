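"""The two multi-scale non-local (MNL) building blocks.

Signal pooling layer
    Three parallel stride-1 max-poolings with windows 1, 2 and 4 extract
    features at three temporal scales from a feature map ``x`` of shape
    ``(w, c)``.  A window-``p`` pool shortens the map to
    ``o = (w - p)/d + 1`` (stride ``d = 1``), so each branch is zero-padded
    back to length ``w`` with ``l = ceil((w - o)/4)`` leading and
    ``r = w - o - l`` trailing zeros before the branches are concatenated
    along the channel axis.  A trainable pointwise convolution then reduces
    the ``3c`` concatenated channels back to ``c`` so the layer is
    shape-preserving (configurable; the raw concatenation is also available).

Multi-scale non-local layer
    Self-attention over the multi-scale channels.  Three pointwise
    convolutions embed the input into phi, delta, rho of shape ``(w, c_hat)``;
    the channel affinity ``R = phi^T delta`` (``c_hat x c_hat``) is softmax
    normalized row-wise into attention weights ``R_hat``; the attended
    features ``rho @ R_hat^T`` (shape ``(w, c_hat)``) pass through an inner
    pointwise convolution back to ``c`` channels, are added residually to the
    input, and a final pointwise convolution produces the output.  A standard
    position-attention variant (``w x w`` affinity) is available behind the
    ``mode`` switch for comparison.

Module-level functions implement each step on a single ``(w, c)`` feature
map; the ``SignalPooling`` and ``MultiScaleNonLocal`` classes are the
trainable, batched layers used inside the network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn.core import Layer, Parameter
from .nn.layers import Conv1d, MaxPool1d
from .nn.optim import softmax

__all__ = [
    "PoolBranchSpec", "pool_branch_spec", "multi_pool", "pad_to_length",
    "signal_pooling_concat", "similarity", "attention_normalize",
    "SignalPooling", "MultiScaleNonLocal", "POOL_WINDOWS",
]

POOL_WINDOWS = (1, 2, 4)


@dataclass(frozen=True)
class PoolBranchSpec:
    """Geometry of one pooling branch: output length and padding split."""
    p: int
    d: int
    o: int
    l: int
    r: int


def pool_branch_spec(w: int, p: int, d: int = 1) -> PoolBranchSpec:
    """Output length and asymmetric zero-padding for a window-``p`` branch.

    ``o = (w - p)/d + 1`` must be integral (it always is for stride 1);
    ``l = ceil((w - o)/4)``, ``r = w - o - l``, so ``o + l + r == w``.
    """
    if not 1 <= p <= w:
        raise ValueError(f"pool window p={p} must be in [1, {w}]")
    num = w - p
    if num % d != 0:
        raise ValueError(f"(w - p)/d is not integral: ({w} - {p})/{d}")
    o = num // d + 1
    l = math.ceil((w - o) / 4)
    r = w - o - l
    assert l >= 0 and r >= 0 and o + l + r == w
    return PoolBranchSpec(p=p, d=d, o=o, l=l, r=r)


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def multi_pool(x: np.ndarray, p: int, d: int = 1) -> np.ndarray:
    """Channelwise sliding-window maximum over a ``(w, c)`` feature map."""
    x2 = _as_2d(x)
    w = x2.shape[0]
    spec = pool_branch_spec(w, p, d)
    out = np.empty((spec.o, x2.shape[1]))
    for t in range(spec.o):
        out[t] = x2[t * d:t * d + p].max(axis=0)
    return out if np.asarray(x).ndim > 1 else out[:, 0]


def pad_to_length(x: np.ndarray, w_target: int) -> np.ndarray:
    """Zero-pad a branch output back to the common length ``w_target``."""
    x2 = _as_2d(x)
    o = x2.shape[0]
    if o > w_target:
        raise ValueError(f"length {o} exceeds target {w_target}")
    l = math.ceil((w_target - o) / 4)
    r = w_target - o - l
    out = np.pad(x2, ((l, r), (0, 0)))
    return out if np.asarray(x).ndim > 1 else out[:, 0]


def signal_pooling_concat(x: np.ndarray, windows=POOL_WINDOWS) -> np.ndarray:
    """Concatenated multi-scale branches of a ``(w, c)`` map: shape ``(w, len(windows)*c)``."""
    x2 = _as_2d(x)
    w = x2.shape[0]
    branches = [pad_to_length(multi_pool(x2, p), w) for p in windows]
    return np.concatenate(branches, axis=1)


def similarity(phi: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Channel affinity ``R = phi^T delta`` for ``(w, c_hat)`` embeddings."""
    phi = np.asarray(phi, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if phi.shape != delta.shape:
        raise ValueError(f"shape mismatch: {phi.shape} vs {delta.shape}")
    return phi.T @ delta


def attention_normalize(r: np.ndarray) -> np.ndarray:
    """Row-wise softmax of the affinity matrix; each row sums to one."""
    return softmax(np.asarray(r, dtype=float), axis=-1)


class SignalPooling(Layer):
    """Trainable signal pooling layer for batches ``(B, w, c)``.

    ``reduce='conv'`` appends a pointwise convolution mapping the
    concatenated ``3c`` channels back to ``c`` (shape-preserving);
    ``reduce='none'`` emits the raw concatenation.
    """

    def __init__(self, channels: int, reduce: str = "conv",
                 windows=POOL_WINDOWS,
                 rng: np.random.Generator | None = None, name: str = "sigpool"):
        if reduce not in ("conv", "none"):
            raise ValueError(f"unknown reduce mode {reduce!r}")
        self.channels = channels
        self.windows = tuple(windows)
        self.reduce = reduce
        self._pools = [MaxPool1d(p, stride=1) for p in self.windows]
        self._pad = None  # per-branch (l, o) for backward
        self.reduce_conv = None
        if reduce == "conv":
            self.reduce_conv = Conv1d(len(self.windows) * channels, channels,
                                      kernel=1, rng=rng, name=f"{name}.reduce")

    def parameters(self) -> list[Parameter]:
        return self.reduce_conv.parameters() if self.reduce_conv else []

    @property
    def out_channels(self) -> int:
        return self.channels if self.reduce == "conv" else len(self.windows) * self.channels

    def output_length(self, w: int) -> int:
        if w < max(self.windows):
            raise ValueError(f"input length {w} shorter than largest window "
                             f"{max(self.windows)}")
        return w

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        w = x.shape[1]
        self.output_length(w)
        branches, pad = [], []
        for p, pool in zip(self.windows, self._pools):
            spec = pool_branch_spec(w, p)
            y = pool.forward(x, train=train)
            branches.append(np.pad(y, ((0, 0), (spec.l, spec.r), (0, 0))))
            pad.append((spec.l, spec.o))
        self._pad = pad
        cat = np.concatenate(branches, axis=2)
        if self.reduce_conv is not None:
            return self.reduce_conv.forward(cat, train=train)
        return cat

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.reduce_conv is not None:
            dout = self.reduce_conv.backward(dout)
        dx = None
        c = self.channels
        for i, pool in enumerate(self._pools):
            l, o = self._pad[i]
            dbranch = dout[:, l:l + o, i * c:(i + 1) * c]
            d = pool.backward(dbranch)
            dx = d if dx is None else dx + d
        return dx


class MultiScaleNonLocal(Layer):
    """Trainable multi-scale non-local attention layer for batches ``(B, w, c)``.

    ``mode='channel'`` computes the literal channel-by-channel affinity
    ``R = phi^T delta``; ``mode='position'`` computes the classical
    position-by-position affinity ``phi delta^T`` instead.
    """

    def __init__(self, channels: int, c_hat: int | None = None,
                 mode: str = "channel",
                 rng: np.random.Generator | None = None, name: str = "nonlocal"):
        if mode not in ("channel", "position"):
            raise ValueError(f"unknown attention mode {mode!r}")
        self.channels = channels
        self.c_hat = c_hat if c_hat is not None else max(1, channels // 2)
        self.mode = mode
        rng = rng if rng is not None else np.random.default_rng(0)
        self.conv_phi = Conv1d(channels, self.c_hat, 1, rng=rng, name=f"{name}.phi")
        self.conv_delta = Conv1d(channels, self.c_hat, 1, rng=rng, name=f"{name}.delta")
        self.conv_rho = Conv1d(channels, self.c_hat, 1, rng=rng, name=f"{name}.rho")
        self.conv_inner = Conv1d(self.c_hat, channels, 1, rng=rng, name=f"{name}.inner")
        self.conv_outer = Conv1d(channels, channels, 1, rng=rng, name=f"{name}.outer")
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [p for conv in (self.conv_phi, self.conv_delta, self.conv_rho,
                               self.conv_inner, self.conv_outer)
                for p in conv.parameters()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        phi = self.conv_phi.forward(x, train=train)      # (B, w, c_hat)
        delta = self.conv_delta.forward(x, train=train)
        rho = self.conv_rho.forward(x, train=train)
        if self.mode == "channel":
            r = np.einsum("bwi,bwj->bij", phi, delta, optimize=True)
            r_hat = softmax(r, axis=-1)
            attended = np.einsum("bwj,bij->bwi", rho, r_hat, optimize=True)
        else:
            r = np.einsum("bwi,bvi->bwv", phi, delta, optimize=True)
            r_hat = softmax(r, axis=-1)
            attended = np.einsum("bwv,bvi->bwi", r_hat, rho, optimize=True)
        inner = self.conv_inner.forward(attended, train=train)
        out = self.conv_outer.forward(inner + x, train=train)
        self._cache = (phi, delta, rho, r_hat)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        phi, delta, rho, r_hat = self._cache
        dz = self.conv_outer.backward(dout)
        dattended = self.conv_inner.backward(dz)
        if self.mode == "channel":
            dr_hat = np.einsum("bwi,bwj->bij", dattended, rho, optimize=True)
            drho = np.einsum("bwi,bij->bwj", dattended, r_hat, optimize=True)
            dr = r_hat * (dr_hat - (dr_hat * r_hat).sum(axis=-1, keepdims=True))
            dphi = np.einsum("bij,bwj->bwi", dr, delta, optimize=True)
            ddelta = np.einsum("bij,bwi->bwj", dr, phi, optimize=True)
        else:
            dr_hat = np.einsum("bwi,bvi->bwv", dattended, rho, optimize=True)
            drho = np.einsum("bwv,bwi->bvi", r_hat, dattended, optimize=True)
            dr = r_hat * (dr_hat - (dr_hat * r_hat).sum(axis=-1, keepdims=True))
            dphi = np.einsum("bwv,bvi->bwi", dr, delta, optimize=True)
            ddelta = np.einsum("bwv,bwi->bvi", dr, phi, optimize=True)
        dx = dz  # residual branch
        dx = dx + self.conv_phi.backward(dphi)
        dx = dx + self.conv_delta.backward(ddelta)
        dx = dx + self.conv_rho.backward(drho)
        return dx
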