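"""AdamW with decoupled weight decay and cosine-annealing learning rate."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Decoupled-weight-decay Adam (amsgrad off)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=1e-2):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data -= self.lr * (update + self.wd * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self):
        return {"t": self.t, "lr": self.lr,
                "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state):
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        for m, src in zip(self.m, state["m"]):
            m[...] = src
        for v, src in zip(self.v, state["v"]):
            v[...] = src


class CosineAnnealingLR:
    """Single-cycle cosine decay from base_lr to eta_min over t_max epochs."""

    def __init__(self, optimizer: AdamW, t_max: int, eta_min: float = 1e-5):
        self.opt = optimizer
        self.base_lr = optimizer.lr
        self.t_max = t_max
        self.eta_min = eta_min
        self.epoch = 0

    def step(self):
        self.epoch += 1
        frac = min(self.epoch, self.t_max) / self.t_max
        self.opt.lr = self.eta_min + 0.5 * (self.base_lr - self.eta_min) \
            * (1.0 + np.cos(np.pi * frac))

    def state_dict(self):
        return {"epoch": self.epoch}

    def load_state_dict(self, state):
        self.epoch = int(state["epoch"])
        if self.epoch:
            frac = min(self.epoch, self.t_max) / self.t_max
            self.opt.lr = self.eta_min + 0.5 * (self.base_lr - self.eta_min) \
                * (1.0 + np.cos(np.pi * frac))
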