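"""SGD with momentum and weight decay, and the poly learning-rate policy."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "poly_lr"]


def poly_lr(base_lr: float, iteration: int, total_iterations: int, power: float = 0.9) -> float:
    """``lr = base_lr * (1 - iter / total_iter) ** power``; reaches 0 at the
    final iteration."""
    if total_iterations <= 0:
        raise ValueError("total_iterations must be positive")
    frac = min(max(iteration / total_iterations, 0.0), 1.0)
    return base_lr * (1.0 - frac) ** power


class SGD:
    """Momentum SGD over the parameter dictionaries of a list of layers."""

    def __init__(self, layers, momentum: float = 0.9, weight_decay: float = 1e-4) -> None:
        self.layers = [l for l in layers if l.params]
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in self.layers
        ]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def step(self, lr: float) -> None:
        for layer, vel in zip(self.layers, self._velocity):
            for k, p in layer.params.items():
                g = layer.grads[k] + self.weight_decay * p
                vel[k] = self.momentum * vel[k] - lr * g
                p += vel[k]
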