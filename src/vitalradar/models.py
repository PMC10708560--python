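"""The four temporal network families: 1D-CNN, TCN, Bi-LSTM and CRNN.

All four share one skeleton: a temporal feature extractor over the raw
baseband sequence, a pooling stage, and a dense head ending in 2 linear
outputs (Fc, Fr regression) or a 3-way softmax (physiological-state
classification). Family-specific extractors:

* ``cnn1d`` — two 128-filter convolutions with 512-tap kernels, each followed
  by max pooling, then a flattened dense head;
* ``tcn``   — six residual blocks of dilated causal convolutions (kernel 3,
  dilations 1, 2, 4, 8, 16, 32), then global average pooling;
* ``bilstm`` — two bidirectional LSTM layers of 128 units with a
  normalization layer between them, then global average pooling;
* ``crnn``  — one 512-tap convolution feeding a 128-unit bidirectional LSTM,
  then global average pooling.

Widths, kernel lengths, pooling sizes, dropout and head shapes are
configurable through :class:`ModelSpec`; the defaults above define the
full-scale variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import scipy.signal

from . import nn
from .datasets import SignalDataset

__all__ = [
    "ModelSpec",
    "ParameterBudget",
    "TemporalModel",
    "build_model",
    "build_cnn1d",
    "build_tcn",
    "build_bilstm",
    "build_crnn",
    "count_parameters",
    "encode_inputs",
]

FAMILIES = ("cnn1d", "tcn", "bilstm", "crnn")
TASKS = ("regression", "classification")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters for one model family and task."""

    family: str
    task: str
    n_samples: int = 5001
    in_channels: int = 2  # (I, Q); 1 in "phase" input mode
    input_mode: str = "iq"  # "iq" | "phase" | "iq_phase"
    conv_filters: int = 128
    kernel_size: int = 512
    conv_stride: int = 1  # the filters see the full-rate input; stride only
                          # decimates the feature maps
    pool_size: int = 4
    crnn_pool: int = 16  # time reduction between the CRNN conv and its LSTM
    tcn_channels: int = 128
    tcn_kernel: int = 3
    tcn_dilations: Tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    tcn_pool: int = 1  # optional boxcar decimation ahead of the TCN stack
    # dropout inside the residual blocks; the head keeps dropout_rate. Twelve
    # noisy layers at the classification learning rate stall convergence, so
    # the in-block rate is kept light by default
    tcn_block_dropout: float = 0.1
    lstm_hidden: int = 128
    lstm_pool: int = 1  # optional boxcar decimation ahead of the pure Bi-LSTM
    head: Tuple[int, ...] = (64, 32)
    dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.input_mode not in ("iq", "phase", "iq_phase"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        expected = {"phase": 1, "iq": 2, "iq_phase": 3}[self.input_mode]
        if self.in_channels != expected:
            object.__setattr__(self, "in_channels", expected)

    @property
    def n_outputs(self) -> int:
        return 3 if self.task == "classification" else 2


@dataclass(frozen=True)
class ParameterBudget:
    total: int
    trainable: int
    non_trainable: int

    def __post_init__(self):
        assert self.total == self.trainable + self.non_trainable


def count_parameters(model) -> ParameterBudget:
    """Exact parameter counts partitioned by trainability."""
    net = model.network if isinstance(model, TemporalModel) else model
    trainable = sum(p.size for p in net.params() if p.trainable)
    frozen = sum(p.size for p in net.params() if not p.trainable)
    return ParameterBudget(trainable + frozen, trainable, frozen)


def _head_layers(n_in: int, spec: ModelSpec, rng) -> list:
    layers = []
    for width in spec.head:
        layers += [nn.Dense(n_in, width, rng), nn.ReLU(),
                   nn.Dropout(spec.dropout_rate, rng)]
        n_in = width
    layers.append(nn.Dense(n_in, spec.n_outputs, rng))
    return layers


def build_cnn1d(spec: ModelSpec, rng=None, dtype=np.float32) -> nn.Sequential:
    if spec.family != "cnn1d":
        raise ValueError("spec.family must be 'cnn1d'")
    rng = rng or np.random.default_rng(spec.seed)
    if spec.n_samples < spec.kernel_size:
        raise ValueError("input shorter than the convolution kernel")
    t = spec.n_samples
    # conv -> BN -> ReLU -> pool, twice; the normalization keeps the flatten
    # activations at unit scale, without which the regression learning rate
    # drives the dense head into a dead (mean-predicting) regime
    s = spec.conv_stride
    layers = [
        nn.Conv1d(spec.in_channels, spec.conv_filters, spec.kernel_size, rng,
                  stride=s, padding="same", dtype=dtype),
        nn.BatchNorm1d(spec.conv_filters, dtype=dtype),
        nn.ReLU(),
        nn.MaxPool1d(spec.pool_size),
        nn.Conv1d(spec.conv_filters, spec.conv_filters, spec.kernel_size, rng,
                  stride=s, padding="same", dtype=dtype),
        nn.BatchNorm1d(spec.conv_filters, dtype=dtype),
        nn.ReLU(),
        nn.MaxPool1d(spec.pool_size),
        nn.Flatten(),
    ]
    t = (-(-t // s)) // spec.pool_size
    t = (-(-t // s)) // spec.pool_size
    layers += _head_layers(t * spec.conv_filters, spec, rng)
    return nn.Sequential(layers)


def build_tcn(spec: ModelSpec, rng=None, dtype=np.float32) -> nn.Sequential:
    if spec.family != "tcn":
        raise ValueError("spec.family must be 'tcn'")
    rng = rng or np.random.default_rng(spec.seed)
    layers = []
    if spec.tcn_pool > 1:
        layers.append(nn.FIRDecimate(spec.tcn_pool, dtype=dtype))
    c_in = spec.in_channels
    for d in sorted(spec.tcn_dilations):
        layers.append(
            nn.TemporalBlock(c_in, spec.tcn_channels, spec.tcn_kernel, d, rng,
                             dropout=spec.tcn_block_dropout, dtype=dtype)
        )
        c_in = spec.tcn_channels
    layers.append(nn.GlobalAvgPool1d())
    layers += _head_layers(spec.tcn_channels, spec, rng)
    return nn.Sequential(layers)


def build_bilstm(spec: ModelSpec, rng=None, dtype=np.float32) -> nn.Sequential:
    if spec.family != "bilstm":
        raise ValueError("spec.family must be 'bilstm'")
    rng = rng or np.random.default_rng(spec.seed)
    h = spec.lstm_hidden
    layers = []
    if spec.lstm_pool > 1:
        layers.append(nn.FIRDecimate(spec.lstm_pool, dtype=dtype))
    layers += [
        nn.BiLSTM(spec.in_channels, h, rng, dtype=dtype),
        nn.BatchNorm1d(2 * h, dtype=dtype),
        nn.BiLSTM(2 * h, h, rng, dtype=dtype),
        nn.GlobalAvgPool1d(),
    ]
    layers += _head_layers(2 * h, spec, rng)
    return nn.Sequential(layers)


def build_crnn(spec: ModelSpec, rng=None, dtype=np.float32) -> nn.Sequential:
    if spec.family != "crnn":
        raise ValueError("spec.family must be 'crnn'")
    rng = rng or np.random.default_rng(spec.seed)
    layers = [
        nn.Conv1d(spec.in_channels, spec.conv_filters, spec.kernel_size, rng,
                  stride=spec.conv_stride, padding="same", dtype=dtype),
        nn.BatchNorm1d(spec.conv_filters, dtype=dtype),
        nn.ReLU(),
        nn.MaxPool1d(spec.crnn_pool),
        nn.BiLSTM(spec.conv_filters, spec.lstm_hidden, rng, dtype=dtype),
        nn.GlobalAvgPool1d(),
    ]
    layers += _head_layers(2 * spec.lstm_hidden, spec, rng)
    return nn.Sequential(layers)


_BUILDERS = {
    "cnn1d": build_cnn1d,
    "tcn": build_tcn,
    "bilstm": build_bilstm,
    "crnn": build_crnn,
}


@dataclass
class TemporalModel:
    """A built network together with its spec and input encoding.

    For regression, targets are standardized per output during training
    (``target_mean``/``target_std`` fitted on the train split) so the two
    rates contribute comparably to the loss despite their different ranges;
    predictions are mapped back to Hz here.
    """

    spec: ModelSpec
    network: nn.Sequential
    target_mean: Optional[np.ndarray] = None
    target_std: Optional[np.ndarray] = None

    def encode(self, dataset_or_iq) -> np.ndarray:
        return encode_inputs(dataset_or_iq, mode=self.spec.input_mode)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode outputs; softmax probabilities for classification."""
        out = self.network.predict(x, batch_size=batch_size)
        if self.spec.task == "classification":
            z = out - out.max(axis=1, keepdims=True)
            ez = np.exp(z)
            return ez / ez.sum(axis=1, keepdims=True)
        if self.target_mean is not None:
            out = out * self.target_std + self.target_mean
        return out

    def predict_dataset(self, ds: SignalDataset, batch_size: int = 256):
        return self.predict(self.encode(ds), batch_size=batch_size)

    def parameter_budget(self) -> ParameterBudget:
        return count_parameters(self.network)


def build_model(spec: ModelSpec, dtype=np.float32) -> TemporalModel:
    net = _BUILDERS[spec.family](spec, dtype=dtype)
    return TemporalModel(spec=spec, network=net)


def encode_inputs(dataset_or_iq, mode: str = "iq") -> np.ndarray:
    """Map complex baseband records to network input channels.

    ``iq``: 2 channels (I, Q), each z-scored per record. ``phase``: one
    channel holding the unwrapped, linearly detrended, z-scored baseband
    angle. ``iq_phase``: all three, giving models both the coherent raw
    quadratures (informative at low SNR) and the demodulated displacement
    (directly exposes the rates at high SNR). Returns float32
    (n, channels, n_samples).
    """
    if isinstance(dataset_or_iq, SignalDataset):
        iq = dataset_or_iq.iq_array()
    else:
        iq = np.asarray(dataset_or_iq)
        if iq.ndim == 1:
            iq = iq[None, :]
    def _phase_channel():
        phase = np.unwrap(np.angle(iq), axis=-1)
        return scipy.signal.detrend(phase, axis=-1, type="linear")

    if mode == "iq":
        x = np.stack([iq.real, iq.imag], axis=1).astype(np.float32)
    elif mode == "phase":
        x = _phase_channel()[:, None, :].astype(np.float32)
    elif mode == "iq_phase":
        x = np.stack([iq.real, iq.imag, _phase_channel()], axis=1).astype(
            np.float32)
    else:
        raise ValueError(f"unknown input mode {mode!r}")
    mean = x.mean(axis=2, keepdims=True)
    std = x.std(axis=2, keepdims=True)
    return (x - mean) / np.maximum(std, 1e-8)
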