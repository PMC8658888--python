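"""Adam with per-group learning rates and exact group freezing.

A frozen group is simply excluded from the update loop, so its parameters
(and its Adam moments) are bitwise untouched no matter how many steps run.
"""

from __future__ import annotations

import numpy as np

from .layers import ParamStore


class Adam:
    def __init__(self, store: ParamStore, group_lrs: dict[str, float],
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.store = store
        self.group_lrs = dict(group_lrs)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.m = {n: np.zeros_like(p.data) for n, p in store.params.items()}
        self.v = {n: np.zeros_like(p.data) for n, p in store.params.items()}
        self.t = {n: 0 for n in store.params}

    def step(self, trainable_groups: set) -> None:
        for name, p in self.store.params.items():
            group = self.store.groups[name]
            if group not in trainable_groups or p.grad is None:
                continue
            lr = self.group_lrs[group]
            self.t[name] += 1
            t = self.t[name]
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            mhat = m / (1 - self.beta1 ** t)
            vhat = v / (1 - self.beta2 ** t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def scale_lrs(self, factor: float) -> None:
        for g in self.group_lrs:
            self.group_lrs[g] *= factor
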