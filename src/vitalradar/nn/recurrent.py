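"""LSTM recurrence with full backpropagation through time.

The cell follows the standard formulation (gate order i, f, g, o; forget-gate
bias initialized to 1). ``BiLSTM`` runs one pass in each time direction and
concatenates the hidden streams along the channel axis.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, Parameter


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Unidirectional LSTM, (B, C, T) -> (B, H, T).

    ``reverse=True`` processes the sequence back-to-front (outputs remain
    aligned with input time indices).
    """

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False, dtype=np.float32):
        self.c_in, self.hidden, self.reverse = c_in, hidden, reverse
        h = hidden
        sx = np.sqrt(1.0 / c_in)
        sh = np.sqrt(1.0 / h)
        self.wx = Parameter(rng.normal(0, sx, (c_in, 4 * h)).astype(dtype), name="wx")
        self.wh = Parameter(rng.normal(0, sh, (h, 4 * h)).astype(dtype), name="wh")
        b = np.zeros(4 * h, dtype=dtype)
        b[h : 2 * h] = 1.0  # forget-gate bias
        self.b = Parameter(b, name="b")

    def params(self):
        return [self.wx, self.wh, self.b]

    def forward(self, x, training=False):
        b, c, t = x.shape
        h = self.hidden
        xs = np.ascontiguousarray(x.transpose(2, 0, 1))  # (T, B, C)
        self._xs = xs
        pre = xs @ self.wx.value + self.b.value  # (T, B, 4H)
        order = range(t - 1, -1, -1) if self.reverse else range(t)
        hs = np.zeros((t, b, h), dtype=x.dtype)
        self._cache = cache = {
            "i": np.empty((t, b, h), dtype=x.dtype),
            "f": np.empty((t, b, h), dtype=x.dtype),
            "g": np.empty((t, b, h), dtype=x.dtype),
            "o": np.empty((t, b, h), dtype=x.dtype),
            "tc": np.empty((t, b, h), dtype=x.dtype),
            "c_prev": np.empty((t, b, h), dtype=x.dtype),
            "h_prev": np.empty((t, b, h), dtype=x.dtype),
        }
        h_t = np.zeros((b, h), dtype=x.dtype)
        c_t = np.zeros((b, h), dtype=x.dtype)
        for ti in order:
            a = pre[ti] + h_t @ self.wh.value
            i_g = _sigmoid(a[:, :h])
            f_g = _sigmoid(a[:, h : 2 * h])
            g_g = np.tanh(a[:, 2 * h : 3 * h])
            o_g = _sigmoid(a[:, 3 * h :])
            cache["c_prev"][ti] = c_t
            cache["h_prev"][ti] = h_t
            c_t = f_g * c_t + i_g * g_g
            tc = np.tanh(c_t)
            h_t = o_g * tc
            cache["i"][ti], cache["f"][ti] = i_g, f_g
            cache["g"][ti], cache["o"][ti] = g_g, o_g
            cache["tc"][ti] = tc
            hs[ti] = h_t
        return np.ascontiguousarray(hs.transpose(1, 2, 0))  # (B, H, T)

    def backward(self, grad_out):
        b, h, t = grad_out.shape
        cache = self._cache
        dhs = grad_out.transpose(2, 0, 1)  # (T, B, H)
        das = np.empty((t, b, 4 * h), dtype=grad_out.dtype)
        dh_next = np.zeros((b, h), dtype=grad_out.dtype)
        dc_next = np.zeros((b, h), dtype=grad_out.dtype)
        order = range(t) if self.reverse else range(t - 1, -1, -1)
        whT = self.wh.value.T
        for ti in order:
            dh = dhs[ti] + dh_next
            i_g, f_g, g_g, o_g = (cache[k][ti] for k in ("i", "f", "g", "o"))
            tc = cache["tc"][ti]
            dc = dh * o_g * (1 - tc * tc) + dc_next
            da = np.empty((b, 4 * h), dtype=grad_out.dtype)
            da[:, :h] = dc * g_g * i_g * (1 - i_g)
            da[:, h : 2 * h] = dc * cache["c_prev"][ti] * f_g * (1 - f_g)
            da[:, 2 * h : 3 * h] = dc * i_g * (1 - g_g * g_g)
            da[:, 3 * h :] = dh * tc * o_g * (1 - o_g)
            das[ti] = da
            dh_next = da @ whT
            dc_next = dc * f_g
        xs = self._xs
        self.wx.grad += np.einsum("tbc,tbk->ck", xs, das, optimize=True)
        self.wh.grad += np.einsum("tbh,tbk->hk", cache["h_prev"], das, optimize=True)
        self.b.grad += das.sum(axis=(0, 1))
        dx = das @ self.wx.value.T  # (T, B, C)
        return np.ascontiguousarray(dx.transpose(1, 2, 0))


class BiLSTM(Layer):
    """Bidirectional LSTM, (B, C, T) -> (B, 2H, T)."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.fwd = LSTM(c_in, hidden, rng, reverse=False, dtype=dtype)
        self.bwd = LSTM(c_in, hidden, rng, reverse=True, dtype=dtype)
        self.hidden = hidden

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x, training=False):
        yf = self.fwd.forward(x, training)
        yb = self.bwd.forward(x, training)
        return np.concatenate([yf, yb], axis=1)

    def backward(self, grad_out):
        h = self.hidden
        dxf = self.fwd.backward(grad_out[:, :h, :])
        dxb = self.bwd.backward(grad_out[:, h:, :])
        return dxf + dxb
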