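"""Optimization: AdamW and a reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np


class AdamW:
    """AdamW with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
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
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class ReduceLROnPlateau:
    """Halve (by ``factor``) the optimizer lr after ``patience`` epochs
    without improvement of the monitored metric.

    ``mode='max'`` treats larger metric values as better (validation mDice).
    An improvement is a strictly better value than the best seen so far.
    """

    def __init__(self, optimizer: AdamW, mode: str = "max", factor: float = 0.5,
                 patience: int = 10, min_lr: float = 0.0):
        if not 0.0 < factor < 1.0:
            raise ValueError("factor must be in (0,1)")
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.optimizer = optimizer
        self.mode = mode
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = None
        self.num_bad_epochs = 0

    def _is_better(self, metric: float) -> bool:
        if self.best is None:
            return True
        return metric > self.best if self.mode == "max" else metric < self.best

    def step(self, metric: float) -> bool:
        """Record one epoch's metric; returns True if the lr was reduced."""
        if self._is_better(metric):
            self.best = metric
            self.num_bad_epochs = 0
            return False
        self.num_bad_epochs += 1
        if self.num_bad_epochs >= self.patience:
            self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
            self.num_bad_epochs = 0
            return True
        return False
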