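"""Adam optimizer over a Module's parameter tree."""

from __future__ import annotations

import numpy as np

from .layers import Module


class Adam:
    """Adaptive-moment optimizer with the standard bias correction."""

    def __init__(self, model: Module, lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for name, mod, key in self.model.named_parameters():
            g = mod.grads.get(key)
            if g is None:
                continue
            g = np.asarray(g, dtype=np.float32)
            m = self.m.setdefault(name, np.zeros_like(mod.params[key]))
            v = self.v.setdefault(name, np.zeros_like(mod.params[key]))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / bc1
            vhat = v / bc2
            mod.params[key] = mod.params[key] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
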