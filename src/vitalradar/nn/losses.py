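"""Training losses: softmax cross-entropy and root-mean-squared error."""

from __future__ import annotations

import numpy as np


class SoftmaxCrossEntropy:
    """Softmax + categorical cross-entropy on logits, mean over the batch."""

    def forward(self, logits: np.ndarray, y_onehot: np.ndarray) -> float:
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        self.probs = ez / ez.sum(axis=1, keepdims=True)
        self._y = y_onehot
        eps = np.finfo(self.probs.dtype).tiny
        return float(-np.mean(np.sum(y_onehot * np.log(self.probs + eps), axis=1)))

    def backward(self) -> np.ndarray:
        return (self.probs - self._y) / self.probs.shape[0]


class RMSELoss:
    """sqrt(mean((pred - y)^2)) over all outputs."""

    def forward(self, pred: np.ndarray, y: np.ndarray) -> float:
        self._diff = pred - y
        self._rmse = float(np.sqrt(np.mean(self._diff**2)))
        return self._rmse

    def backward(self) -> np.ndarray:
        denom = max(self._rmse, 1e-12) * self._diff.size
        return self._diff / denom
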