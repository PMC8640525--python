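"""Optimizers and the softmax cross-entropy loss."""

from __future__ import annotations

import numpy as np

from ..errors import InvalidArgumentError
from .network import Network, softmax


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = len(labels)
    eps = 1e-12
    loss = -float(np.mean(np.log(probs[np.arange(n), labels] + eps)))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class RMSprop:
    """RMSprop with the usual exponentially-decayed squared-gradient cache."""

    def __init__(self, net: Network, learning_rate: float, rho: float = 0.9, eps: float = 1e-7):
        if learning_rate <= 0:
            raise InvalidArgumentError("learning_rate must be positive")
        self.net = net
        self.lr = learning_rate
        self.rho = rho
        self.eps = eps
        self.cache: dict[str, np.ndarray] = {}

    def step(self) -> None:
        for layer in self.net.layers:
            params, grads = layer.params(), layer.grads()
            for pname, w in params.items():
                key = f"{layer.name}/{pname}"
                g = grads[pname]
                c = self.cache.get(key)
                if c is None:
                    c = np.zeros_like(w)
                c = self.rho * c + (1.0 - self.rho) * g * g
                self.cache[key] = c
                w -= self.lr * g / (np.sqrt(c) + self.eps)


class SGD:
    """Plain mini-batch gradient descent (no momentum)."""

    def __init__(self, net: Network, learning_rate: float):
        if learning_rate <= 0:
            raise InvalidArgumentError("learning_rate must be positive")
        self.net = net
        self.lr = learning_rate

    def step(self) -> None:
        for layer in self.net.layers:
            grads = layer.grads()
            for pname, w in layer.params().items():
                w -= self.lr * grads[pname]


OPTIMIZERS = {"rmsprop": RMSprop, "sgd": SGD}
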