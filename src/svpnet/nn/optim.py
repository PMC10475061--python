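"""First-order optimisers operating on lists of parameter tensors."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Optimizer:
    def __init__(self, params: list[Tensor], lr: float):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        raise NotImplementedError


class SGD(Optimizer):
    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


class RMSprop(Optimizer):
    def __init__(self, params, lr: float, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(params, lr)
        self.rho = rho
        self.eps = eps
        self.sq = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, s in zip(self.params, self.sq):
            if p.grad is None:
                continue
            s *= self.rho
            s += (1.0 - self.rho) * p.grad * p.grad
            p.data -= self.lr * p.grad / (np.sqrt(s) + self.eps)


class Adam(Optimizer):
    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad * p.grad
            p.data -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def make(name: str, params, lr: float) -> Optimizer:
    table = {"sgd": SGD, "rmsprop": RMSprop, "adam": Adam}
    try:
        return table[name.lower()](params, lr)
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; expected one of {sorted(table)}")
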