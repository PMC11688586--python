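"""Adam optimizer and static loss scaling."""

from __future__ import annotations

import numpy as np

from .modules import Parameter


class Adam:
    def __init__(
        self,
        params: list[Parameter],
        lr: float = 3e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bias1
            vhat = self.v[i] / bias2
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v, "lr": self.lr}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(a) for a in state["m"]]
        self.v = [np.asarray(a) for a in state["v"]]
        self.lr = float(state["lr"])


class GradScaler:
    """Static loss scaling: multiply the loss before backward, divide the
    gradients before the optimizer step.  Neutral in full precision; kept as
    the gradient-scaling stage of the training procedure."""

    def __init__(self, scale: float = 1024.0, enabled: bool = True):
        self.scale = float(scale)
        self.enabled = enabled

    def scale_loss(self, loss):
        return loss * self.scale if self.enabled else loss

    def unscale(self, params) -> None:
        if not self.enabled:
            return
        inv = 1.0 / self.scale
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * inv
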