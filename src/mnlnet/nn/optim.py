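"""Adam optimizer and the softmax cross-entropy training head."""

from __future__ import annotations

import numpy as np

from .core import Parameter

__all__ = ["Adam", "SoftmaxCrossEntropy", "softmax"]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (shift-invariant in the logits)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class SoftmaxCrossEntropy:
    """Mean cross-entropy over a batch, fused with the softmax output layer."""

    def __init__(self):
        self._cache = None

    def forward(self, logits: np.ndarray, labels: np.ndarray) -> float:
        probs = softmax(logits)
        n = logits.shape[0]
        eps = 1e-12
        loss = -np.log(probs[np.arange(n), labels] + eps).mean()
        self._cache = (probs, labels)
        return float(loss)

    def backward(self) -> np.ndarray:
        probs, labels = self._cache
        n = probs.shape[0]
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        return grad / n


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad ** 2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
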