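"""Optimisers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "StepLR", "lr_at_epoch"]


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.data -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for dst, src in zip(self.m, state["m"]):
            dst[...] = src
        for dst, src in zip(self.v, state["v"]):
            dst[...] = src


def lr_at_epoch(epoch: int, base_lr: float, step_size: int, gamma: float) -> float:
    """Closed form of the step decay schedule: base_lr * gamma**floor(epoch/step).

    The default recipe starts at 1e-4 and multiplies by 0.1 every 7 epochs.
    """
    if epoch < 0:
        raise ValueError(f"epoch must be >= 0, got {epoch}")
    if step_size < 1:
        raise ValueError(f"step_size must be >= 1, got {step_size}")
    if not 0 < gamma <= 1:
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    if base_lr <= 0:
        raise ValueError(f"base_lr must be > 0, got {base_lr}")
    return base_lr * gamma ** (epoch // step_size)


class StepLR:
    """Stateful step-decay scheduler driving an Adam instance per epoch."""

    def __init__(self, optimizer: Adam, base_lr: float, step_size: int, gamma: float):
        self.optimizer = optimizer
        self.base_lr = base_lr
        self.step_size = step_size
        self.gamma = gamma
        self.set_epoch(0)

    def set_epoch(self, epoch: int) -> float:
        self.optimizer.lr = lr_at_epoch(epoch, self.base_lr, self.step_size, self.gamma)
        return self.optimizer.lr
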