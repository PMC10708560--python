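"""Residual block of dilated causal convolutions (TCN building block)."""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm1d, Conv1d, Dropout, Layer, ReLU


class TemporalBlock(Layer):
    """conv-BN-ReLU-dropout twice, plus a (1x1-projected) residual connection.

    Both convolutions are causal with the same dilation, so a perturbation at
    time t can only influence outputs at times >= t (checked in evaluation
    mode, where batch normalization is a pointwise affine map).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator, dropout: float = 0.0,
                 dtype=np.float32):
        # BN follows each conv, so conv biases would be redundant (zero-gradient)
        self.conv1 = Conv1d(c_in, c_out, kernel, rng, dilation=dilation,
                            padding="causal", bias=False, dtype=dtype)
        self.bn1 = BatchNorm1d(c_out, dtype=dtype)
        self.relu1 = ReLU()
        self.drop1 = Dropout(dropout, rng)
        self.conv2 = Conv1d(c_out, c_out, kernel, rng, dilation=dilation,
                            padding="causal", bias=False, dtype=dtype)
        self.bn2 = BatchNorm1d(c_out, dtype=dtype)
        self.relu2 = ReLU()
        self.drop2 = Dropout(dropout, rng)
        self.proj = (
            Conv1d(c_in, c_out, 1, rng, padding="valid", bias=False, dtype=dtype)
            if c_in != c_out
            else None
        )
        self.relu_out = ReLU()
        self._main = [self.conv1, self.bn1, self.relu1, self.drop1,
                      self.conv2, self.bn2, self.relu2, self.drop2]

    def params(self):
        out = []
        for layer in self._main + ([self.proj] if self.proj is not None else []):
            out += layer.params()
        return out

    def forward(self, x, training=False):
        y = x
        for layer in self._main:
            y = layer.forward(y, training)
        res = self.proj.forward(x, training) if self.proj is not None else x
        return self.relu_out.forward(y + res, training)

    def backward(self, grad_out):
        g = self.relu_out.backward(grad_out)
        gres = self.proj.backward(g) if self.proj is not None else g
        gy = g
        for layer in reversed(self._main):
            gy = layer.backward(gy)
        return gy + gres
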