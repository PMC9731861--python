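"""Adam optimizer with cosine-annealed learning rate."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.base_lr = lr
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CosineAnnealing:
    """lr(t) = lr_min + (lr0 - lr_min) * (1 + cos(pi * t / T)) / 2."""

    def __init__(self, optimizer: Adam, total_epochs: int, lr_min: float = 0.0):
        self.opt = optimizer
        self.T = max(1, total_epochs)
        self.lr_min = lr_min
        self.epoch = 0

    def step(self) -> None:
        self.epoch += 1
        frac = min(self.epoch, self.T) / self.T
        self.opt.lr = self.lr_min + (self.opt.base_lr - self.lr_min) * \
            0.5 * (1.0 + np.cos(np.pi * frac))
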