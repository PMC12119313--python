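"""SGD with momentum, weight decay, and global-norm gradient clipping."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .tensor import Tensor

__all__ = ["SGD", "clip_grad_norm"]


def clip_grad_norm(params: Sequence[Tensor], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``.

    Returns the pre-clip norm.
    """
    if max_norm <= 0:
        raise ValueError("max_norm must be positive")
    sq = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        sq += float(np.sum(g * g))
    total = float(np.sqrt(sq))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total


class SGD:
    """Classic SGD: v <- mu*v + g + wd*p ; p <- p - lr*v."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v
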