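"""Feed-forward layers: dense, convolutional, pooling, normalization.

Conv1d implements cross-correlation with ``same``/``causal``/``valid``
padding, stride and dilation. Two execution paths produce identical results:
a slice-gather path for short kernels (dilated kernel-3 stacks) and an
FFT-domain path for long kernels (the 512-tap front-end convolutions), both
with exact adjoint backward passes.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
import scipy.fft


class Parameter:
    """A weight array with its gradient accumulator."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, trainable: bool = True, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.trainable = trainable
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self) -> List[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)
        self.w = Parameter(rng.normal(0, scale, (n_in, n_out)).astype(dtype), name="w")
        self.b = Parameter(np.zeros(n_out, dtype=dtype), name="b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad_out):
        self.w.grad += self._x.T @ grad_out
        self.b.grad += grad_out.sum(axis=0)
        return grad_out @ self.w.value.T


class ReLU(Layer):
    def forward(self, x, training=False):
        y = np.maximum(x, 0)
        self._mask = y > 0
        return y

    def backward(self, grad_out):
        return grad_out * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad_out):
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class GlobalAvgPool1d(Layer):
    """(B, C, T) -> (B, C), averaging over time."""

    def forward(self, x, training=False):
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad_out):
        return np.repeat(grad_out[:, :, None], self._t, axis=2) / self._t


class AvgPool1d(Layer):
    """Non-overlapping boxcar average over time (truncates the remainder)."""

    def __init__(self, pool: int):
        if pool < 1:
            raise ValueError("pool must be >= 1")
        self.pool = pool

    def forward(self, x, training=False):
        b, c, t = x.shape
        t_out = t // self.pool
        self._t_in = t
        y = x[:, :, : t_out * self.pool].reshape(b, c, t_out, self.pool)
        return y.mean(axis=3)

    def backward(self, grad_out):
        b, c, t_out = grad_out.shape
        dx = np.zeros((b, c, self._t_in), dtype=grad_out.dtype)
        dx[:, :, : t_out * self.pool] = np.repeat(
            grad_out[:, :, :, None] / self.pool, self.pool, axis=3
        ).reshape(b, c, t_out * self.pool)
        return dx


class MaxPool1d(Layer):
    """Non-overlapping max pooling over time (truncates the remainder)."""

    def __init__(self, pool: int):
        if pool < 1:
            raise ValueError("pool must be >= 1")
        self.pool = pool

    def forward(self, x, training=False):
        b, c, t = x.shape
        t_out = t // self.pool
        self._t_in = t
        xr = x[:, :, : t_out * self.pool].reshape(b, c, t_out, self.pool)
        y = xr.max(axis=3)
        self._xr, self._y = xr, y
        return y

    def backward(self, grad_out):
        # route gradient to the max position(s); exact ties share it equally
        b, c, t_out = grad_out.shape
        mask = self._xr == self._y[:, :, :, None]
        counts = mask.sum(axis=3, dtype=grad_out.dtype)
        dxr = mask * (grad_out / counts)[:, :, :, None]
        dx = np.zeros((b, c, self._t_in), dtype=grad_out.dtype)
        dx[:, :, : t_out * self.pool] = dxr.reshape(b, c, t_out * self.pool)
        return dx


class BatchNorm1d(Layer):
    """Batch normalization over the channel axis for (B, C, T) or (B, C).

    Running mean/variance are tracked as non-trainable parameters and used in
    evaluation mode, so inference is a pointwise (causality-preserving) affine
    transform.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Parameter(np.ones(channels, dtype=dtype), name="gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype), name="beta")
        self.running_mean = Parameter(np.zeros(channels, dtype=dtype),
                                      trainable=False, name="running_mean")
        self.running_var = Parameter(np.ones(channels, dtype=dtype),
                                     trainable=False, name="running_var")
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def _reshape(self, v, ndim):
        return v[None, :, None] if ndim == 3 else v[None, :]

    def forward(self, x, training=False):
        axes = (0, 2) if x.ndim == 3 else (0,)
        self._axes = axes
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean.value[...] = m * self.running_mean.value + (1 - m) * mean
            self.running_var.value[...] = m * self.running_var.value + (1 - m) * var
        else:
            mean = self.running_mean.value
            var = self.running_var.value
        r = lambda v: self._reshape(v, x.ndim)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - r(mean)) * r(self._inv_std)
        self._training = training
        return r(self.gamma.value) * self._xhat + r(self.beta.value)

    def backward(self, grad_out):
        axes = self._axes
        r = lambda v: self._reshape(v, grad_out.ndim)
        s1 = grad_out.sum(axis=axes)
        s2 = (grad_out * self._xhat).sum(axis=axes)
        self.gamma.grad += s2
        self.beta.grad += s1
        scale = self.gamma.value * self._inv_std
        if not self._training:
            return grad_out * r(scale)
        m = np.prod([grad_out.shape[a] for a in axes])
        return (grad_out - r(s1 / m) - self._xhat * r(s2 / m)) * r(scale)


class Conv1d(Layer):
    """1-D cross-correlation layer, (B, C_in, T) -> (B, C_out, T_out)."""

    # actual taps above which the FFT path wins; dilated short kernels stay on
    # the gather path (cost scales with tap count), which is also exactly
    # causal sample-for-sample (no FFT rounding spread)
    FFT_KERNEL_THRESHOLD = 24

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, dilation: int = 1,
                 padding: str = "same", bias: bool = True, dtype=np.float32):
        if padding not in ("same", "causal", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        if kernel < 1 or stride < 1 or dilation < 1:
            raise ValueError("kernel, stride and dilation must be >= 1")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.stride, self.dilation, self.padding = stride, dilation, padding
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = Parameter(
            rng.normal(0, scale, (c_out, c_in, kernel)).astype(dtype), name="w"
        )
        self.b = Parameter(np.zeros(c_out, dtype=dtype), name="b") if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    # -- geometry -------------------------------------------------------------
    @property
    def k_eff(self) -> int:
        return (self.kernel - 1) * self.dilation + 1

    def _pads(self, t: int):
        ke = self.k_eff
        if self.padding == "same":
            pl = (ke - 1) // 2
            pr = ke - 1 - pl
        elif self.padding == "causal":
            pl, pr = ke - 1, 0
        else:
            pl = pr = 0
        t_full = t + pl + pr - ke + 1
        if t_full < 1:
            raise ValueError(f"input length {t} shorter than kernel span {ke}")
        return pl, pr, t_full

    def _dilated_weight(self):
        if self.dilation == 1:
            return self.w.value
        wd = np.zeros((self.c_out, self.c_in, self.k_eff), dtype=self.w.value.dtype)
        wd[:, :, :: self.dilation] = self.w.value
        return wd

    # -- forward --------------------------------------------------------------
    def forward(self, x, training=False):
        b, ci, t = x.shape
        if ci != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {ci}")
        pl, pr, t_full = self._pads(t)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x
        self._xp, self._t_in, self._pl, self._t_full = xp, t, pl, t_full
        if self.kernel >= self.FFT_KERNEL_THRESHOLD:
            y_full = self._forward_fft(xp, t_full)
        else:
            y_full = self._forward_gather(xp, t_full)
        y = y_full[:, :, :: self.stride] if self.stride > 1 else y_full
        if self.b is not None:
            y = y + self.b.value[None, :, None]
        return y

    def _forward_gather(self, xp, t_full):
        # one large (B*T, Ci*K) @ (Ci*K, Co) GEMM instead of per-sample
        # batched products; cols layout (B, T, Ci, K)
        b = xp.shape[0]
        k, d = self.kernel, self.dilation
        cols = np.empty((b, t_full, self.c_in, k), dtype=xp.dtype)
        for i in range(k):
            cols[:, :, :, i] = xp[:, :, i * d : i * d + t_full].transpose(0, 2, 1)
        self._cols2d = cols.reshape(b * t_full, self.c_in * k)
        w2 = self.w.value.reshape(self.c_out, self.c_in * k)
        y = self._cols2d @ w2.T  # (B*T, Co)
        return np.ascontiguousarray(
            y.reshape(b, t_full, self.c_out).transpose(0, 2, 1)
        )

    def _forward_fft(self, xp, t_full):
        n = scipy.fft.next_fast_len(xp.shape[2])
        self._nfft = n
        self._xf = scipy.fft.rfft(xp, n=n, axis=2)
        wd = self._dilated_weight()
        self._wf = scipy.fft.rfft(wd, n=n, axis=2)
        yf = np.einsum("bif,oif->bof", self._xf, np.conj(self._wf), optimize=True)
        y = scipy.fft.irfft(yf, n=n, axis=2)[:, :, :t_full]
        return y.astype(xp.dtype, copy=False)

    # -- backward -------------------------------------------------------------
    def backward(self, grad_out):
        if self.b is not None:
            self.b.grad += grad_out.sum(axis=(0, 2))
        if self.stride > 1:
            dy_full = np.zeros(
                (grad_out.shape[0], self.c_out, self._t_full), dtype=grad_out.dtype
            )
            dy_full[:, :, :: self.stride] = grad_out
        else:
            dy_full = grad_out
        if self.kernel >= self.FFT_KERNEL_THRESHOLD:
            dxp = self._backward_fft(dy_full)
        else:
            dxp = self._backward_gather(dy_full)
        pl = self._pl
        return dxp[:, :, pl : pl + self._t_in]

    def _backward_gather(self, dy_full):
        k, d, t_full = self.kernel, self.dilation, self._t_full
        b = dy_full.shape[0]
        dy2d = np.ascontiguousarray(dy_full.transpose(0, 2, 1)).reshape(
            b * t_full, self.c_out
        )
        dw2 = dy2d.T @ self._cols2d  # (Co, Ci*K)
        self.w.grad += dw2.reshape(self.c_out, self.c_in, k)
        w2 = self.w.value.reshape(self.c_out, self.c_in * k)
        dcols = (dy2d @ w2).reshape(b, t_full, self.c_in, k)
        dxp = np.zeros_like(self._xp)
        for i in range(k):
            dxp[:, :, i * d : i * d + t_full] += dcols[:, :, :, i].transpose(0, 2, 1)
        return dxp

    def _backward_fft(self, dy_full):
        n = self._nfft
        dyf = scipy.fft.rfft(dy_full, n=n, axis=2)
        # weight gradient: cross-correlation of the padded input with dy
        dwf = np.einsum("bof,bif->oif", np.conj(dyf), self._xf, optimize=True)
        dwd = scipy.fft.irfft(dwf, n=n, axis=2)[:, :, : self.k_eff]
        if self.dilation == 1:
            self.w.grad += dwd.astype(self.w.grad.dtype, copy=False)
        else:
            self.w.grad += dwd[:, :, :: self.dilation].astype(
                self.w.grad.dtype, copy=False
            )
        # input gradient: full convolution of dy with the (dilated) kernel
        dxf = np.einsum("bof,oif->bif", dyf, self._wf, optimize=True)
        dxp = scipy.fft.irfft(dxf, n=n, axis=2)[:, :, : self._xp.shape[2]]
        return dxp.astype(self._xp.dtype, copy=False)


class FIRDecimate(Layer):
    """Anti-aliased decimation: fixed Kaiser-windowed lowpass, then stride.

    Unlike a boxcar average, the passband is flat up to ~0.8/q of the
    decimated Nyquist, so band content near the new Nyquist is preserved.
    The filter is fixed (not trained) and applied per channel.
    """

    def __init__(self, q: int, dtype=np.float32):
        if q < 1:
            raise ValueError("q must be >= 1")
        import scipy.signal

        self.q = q
        # cutoff at 0.8 of the decimated Nyquist: flat passband with solid
        # stopband rejection. A wider passband trades attenuation near the
        # new Nyquist against folded stopband leakage and is not worth it;
        # a boxcar average (sinc response) droops the passband badly
        taps = 8 * q + 1
        self.h = scipy.signal.firwin(taps, 0.8 / q, window=("kaiser", 8.0)
                                     ).astype(dtype)

    def forward(self, x, training=False):
        if self.q == 1:
            return x
        k = len(self.h)
        pl = (k - 1) // 2
        pr = k - 1 - pl
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        self._t_in, self._pl = x.shape[2], pl
        windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        self._sel = np.arange(0, x.shape[2], self.q)
        return np.einsum("bctk,k->bct", windows[:, :, self._sel, :], self.h,
                         optimize=True)

    def backward(self, grad_out):
        if self.q == 1:
            return grad_out
        k = len(self.h)
        b, c, _ = grad_out.shape
        dxp = np.zeros((b, c, self._t_in + k - 1), dtype=grad_out.dtype)
        for i in range(k):
            np.add.at(dxp, (slice(None), slice(None), self._sel + i),
                      grad_out * self.h[i])
        return dxp[:, :, self._pl : self._pl + self._t_in]
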