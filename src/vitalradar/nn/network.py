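"""Sequential container with explicit forward/backward and weight I/O."""

from __future__ import annotations

from typing import List

import numpy as np

from .layers import Layer, Parameter


class Sequential(Layer):
    def __init__(self, layers: List[Layer]):
        self.layers = list(layers)

    def params(self) -> List[Parameter]:
        out = []
        for layer in self.layers:
            out += layer.params()
        return out

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def predict(self, x, batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode forward pass in batches."""
        outs = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    # -- weight (de)serialization --------------------------------------------
    def state_dict(self) -> dict:
        return {f"p{i}": p.value for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            v = np.asarray(state[f"p{i}"])
            if v.shape != p.value.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.value[...] = v

    def save_weights(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data))

    def weight_checksum(self) -> float:
        return float(sum(np.abs(p.value).sum() for p in self.params()))
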