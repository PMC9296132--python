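"""SGD with momentum and selective weight decay."""

from __future__ import annotations

import numpy as np

from .layers import Param


class SGD:
    """Momentum SGD; weight decay applies only to ``kind == "weight"`` params.

    Batch-norm scales/offsets and biases are excluded from decay, the
    standard convention for contrastive training recipes.
    """

    def __init__(self, params: list[Param], momentum: float = 0.9,
                 weight_decay: float = 1e-4):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.buffers = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float) -> None:
        for p, buf in zip(self.params, self.buffers):
            g = p.grad
            if self.weight_decay and p.kind == "weight":
                g = g + self.weight_decay * p.value
            buf *= self.momentum
            buf += g
            p.value -= lr * buf

    def state_dict(self) -> dict:
        return {f"buf{i}": b for i, b in enumerate(self.buffers)}

    def load_state_dict(self, state: dict) -> None:
        for i, buf in enumerate(self.buffers):
            buf[...] = state[f"buf{i}"]
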