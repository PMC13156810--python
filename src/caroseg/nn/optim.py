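"""SGD with Nesterov momentum and the polynomial learning-rate decay."""

from __future__ import annotations

import numpy as np

__all__ = ["poly_lr", "clip_grad_norm", "SGDNesterov"]


def poly_lr(epoch: int, total_epochs: int, initial_lr: float = 0.01, exponent: float = 0.9) -> float:
    """Polynomial decay ``initial_lr * (1 - epoch/total)**exponent``.

    Starts at ``initial_lr`` for epoch 0, decays strictly monotonically to 0
    at ``total_epochs``.
    """
    if not (0 <= epoch <= total_epochs):
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs}]")
    return float(initial_lr * (1.0 - epoch / total_epochs) ** exponent)


def clip_grad_norm(layers, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for layer in layers:
        for g in layer.grads.values():
            total += float((g.astype(np.float64) ** 2).sum())
    norm = float(np.sqrt(total))
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for layer in layers:
            for k in layer.grads:
                layer.grads[k] *= scale
    return norm


class SGDNesterov:
    """Stochastic gradient descent with Nesterov momentum.

    Update (PyTorch convention): ``v = mu*v + g``; ``p -= lr * (g + mu*v)``.
    """

    def __init__(self, layers, momentum: float = 0.99) -> None:
        self.layers = list(layers)
        self.mu = momentum
        self.velocity: list[dict[str, np.ndarray]] = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in self.layers
        ]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def step(self, lr: float) -> None:
        for layer, vel in zip(self.layers, self.velocity):
            for k, p in layer.params.items():
                g = layer.grads[k]
                v = vel[k]
                v *= self.mu
                v += g
                p -= (lr * (g + self.mu * v)).astype(p.dtype)

    def state_dict(self) -> dict:
        return {
            "momentum": self.mu,
            "velocity": [{k: v.copy() for k, v in vel.items()} for vel in self.velocity],
        }

    def load_state_dict(self, state: dict) -> None:
        self.mu = state["momentum"]
        for vel, sv in zip(self.velocity, state["velocity"]):
            for k in vel:
                vel[k] = sv[k].copy()
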