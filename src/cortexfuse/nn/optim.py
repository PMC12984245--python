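"""Optimisers and learning-rate schedules."""

from __future__ import annotations

import math

import numpy as np


class AdamW:
    """Decoupled weight-decay Adam.

    ``param_groups`` is a list of dicts with keys ``params`` (list of
    Parameters) and optional ``lr_scale`` (relative learning-rate multiplier,
    used e.g. to train a fine-tuned trunk at lr/1000).
    """

    def __init__(self, params_or_groups, lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        if isinstance(params_or_groups, (list, tuple)) and params_or_groups \
                and isinstance(params_or_groups[0], dict):
            self.param_groups = [dict(g) for g in params_or_groups]
        else:
            self.param_groups = [{"params": list(params_or_groups)}]
        for g in self.param_groups:
            g.setdefault("lr_scale", 1.0)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._state = {}
        self._t = 0

    def zero_grad(self):
        for g in self.param_groups:
            for p in g["params"]:
                p.grad = None

    def step(self):
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for group in self.param_groups:
            lr = self.lr * group["lr_scale"]
            for p in group["params"]:
                if p.grad is None:
                    continue
                st = self._state.get(id(p))
                if st is None:
                    st = {"m": np.zeros_like(p.data), "v": np.zeros_like(p.data)}
                    self._state[id(p)] = st
                g = p.grad
                st["m"] = b1 * st["m"] + (1 - b1) * g
                st["v"] = b2 * st["v"] + (1 - b2) * g * g
                mhat = st["m"] / bc1
                vhat = st["v"] / bc2
                p.data = p.data - lr * (mhat / (np.sqrt(vhat) + self.eps)
                                        + self.weight_decay * p.data)


def cosine_lr(step: int, total_steps: int, lr_start: float, lr_end: float) -> float:
    """Cosine decay from ``lr_start`` to ``lr_end`` over ``total_steps``."""
    if total_steps <= 1:
        return lr_end
    t = min(max(step, 0), total_steps - 1) / (total_steps - 1)
    return lr_end + 0.5 * (lr_start - lr_end) * (1.0 + math.cos(math.pi * t))
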