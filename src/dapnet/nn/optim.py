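"""Adam optimizer and step learning-rate schedule."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "step_lr"]


def step_lr(lr_initial: float, epoch: int, decay_factor: float = 0.1,
            decay_every: int = 20) -> float:
    """lr after ``epoch`` completed epochs: lr0 * factor^floor(epoch/every)."""
    return lr_initial * decay_factor ** (epoch // decay_every)


class Adam:
    """Adam with classic L2 weight decay folded into the gradient."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
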