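"""Adam optimizer over a Sequential model's trainable parameters."""

from __future__ import annotations

import numpy as np


class Adam:
    """Standard Adam (Kingma & Ba) with bias correction.

    Built against a model: the entry list is fixed at construction, so
    layers frozen before building the optimizer are never touched.
    """

    def __init__(self, model, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.entries = model.trainable_parameters()
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.entries]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.entries]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, name) in enumerate(self.entries):
            g = layer.grads[name]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
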