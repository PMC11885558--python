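"""Optimizers and learning-rate schedulers for the training harness.

RAdam follows Liu et al.'s rectified Adam update: while the estimated
variance of the adaptive term is untrustworthy (early steps), it falls back
to plain momentum SGD; afterwards it applies the variance rectification
factor r_t.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor


class RAdam:
    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        t = self.t
        b1, b2 = self.b1, self.b2
        bias1 = 1.0 - b1 ** t
        bias2 = 1.0 - b2 ** t
        rho_t = self.rho_inf - 2.0 * t * b2 ** t / bias2
        if rho_t > 5.0:
            r = math.sqrt(((rho_t - 4) * (rho_t - 2) * self.rho_inf)
                          / ((self.rho_inf - 4) * (self.rho_inf - 2) * rho_t))
        else:
            r = None
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / bias1
            if r is not None:
                vhat = np.sqrt(v / bias2) + self.eps
                p.data = p.data - (self.lr * r) * mhat / vhat
            else:
                p.data = p.data - self.lr * mhat


class CosineAnnealingWarmRestarts:
    """Epoch-stepped cosine schedule with warm restarts (T_0, T_mult)."""

    def __init__(self, optimizer, t0: int = 10, t_mult: int = 2,
                 eta_min: float = 0.0):
        self.opt = optimizer
        self.base_lr = optimizer.lr
        self.t0, self.t_mult, self.eta_min = t0, t_mult, eta_min
        self.t_cur = 0
        self.t_i = t0

    def step(self):
        self.t_cur += 1
        if self.t_cur >= self.t_i:
            self.t_cur = 0
            self.t_i *= self.t_mult
        self.opt.lr = self.eta_min + (self.base_lr - self.eta_min) * (
            1 + math.cos(math.pi * self.t_cur / self.t_i)) / 2


class ExponentialLR:
    def __init__(self, optimizer, gamma: float = 0.98):
        self.opt = optimizer
        self.gamma = gamma

    def step(self):
        self.opt.lr *= self.gamma


def make_scheduler(name: str, optimizer):
    if name == "cosine_warm_restarts":
        return CosineAnnealingWarmRestarts(optimizer)
    if name == "exponential":
        return ExponentialLR(optimizer)
    if name in ("none", None, ""):
        return None
    raise ValueError(f"unknown scheduler {name!r}")
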