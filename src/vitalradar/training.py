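"""Training loop and evaluation protocol for the temporal models.

Regression models minimize RMSE with Adam at learning rate 0.001;
classification models minimize categorical cross-entropy at 0.0001. Both
train for a fixed number of epochs (60 at full scale, no early stopping)
with batch size 64. Test metrics can be averaged over repeated train/test
compilations (default 10), reported as mean +/- standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import nn
from .datasets import SignalDataset, derive_seed
from .metrics import MetricsReport, classification_metrics, r2_star, regression_metrics
from .models import ModelSpec, TemporalModel, build_model

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "train",
    "evaluate",
    "repeated_evaluation",
    "state_r2star_report",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 60
    batch_size: int = 64
    lr: Optional[float] = None  # default: 1e-3 regression, 1e-4 classification
    seed: int = 0
    n_test_repeats: int = 10
    #: average the weights of the last k epochs for evaluation (0 = use the
    #: final-epoch weights). Tail averaging damps the epoch-to-epoch jitter of
    #: fixed-epoch training; used by the reduced desk scale
    tail_average_epochs: int = 0
    verbose: bool = False

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr is not None and self.lr <= 0:
            raise ValueError("lr must be > 0")

    def resolved_lr(self, task: str) -> float:
        if self.lr is not None:
            return self.lr
        return 1e-3 if task == "regression" else 1e-4


@dataclass
class TrainHistory:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": np.arange(1, len(self.train_loss) + 1),
             "train_loss": self.train_loss, "val_loss": self.val_loss}
        )


def _targets(ds: SignalDataset, task: str) -> np.ndarray:
    if task == "regression":
        return ds.rate_labels().astype(np.float32)
    return ds.one_hot_labels().astype(np.float32)


def train(model: TemporalModel, dataset: SignalDataset,
          cfg: TrainConfig = TrainConfig()) -> TrainHistory:
    """Fit ``model`` on the dataset's train split, tracking validation loss.

    Returns the per-epoch loss history; the model keeps its final-epoch
    weights (fixed-epoch protocol, no early stopping).
    """
    if model.spec.task != dataset.task:
        raise ValueError(
            f"task mismatch: model {model.spec.task!r} vs dataset {dataset.task!r}"
        )
    train_ds = dataset.subset("train")
    val_ds = dataset.subset("val")
    x_train = model.encode(train_ds)
    y_train = _targets(train_ds, dataset.task)
    x_val = model.encode(val_ds)
    y_val = _targets(val_ds, dataset.task)
    if dataset.task == "regression":
        # standardize targets so Fc (range ~1.2 Hz) does not drown Fr (~0.2 Hz)
        model.target_mean = y_train.mean(axis=0)
        model.target_std = np.maximum(y_train.std(axis=0), 1e-8)
        y_train = (y_train - model.target_mean) / model.target_std
        y_val = (y_val - model.target_mean) / model.target_std

    loss_fn = (nn.RMSELoss() if dataset.task == "regression"
               else nn.SoftmaxCrossEntropy())
    opt = nn.Adam(model.network.params(), lr=cfg.resolved_lr(dataset.task))
    rng = np.random.default_rng(derive_seed(cfg.seed, "shuffle"))
    history = TrainHistory()
    n = len(x_train)
    tail_k = min(cfg.tail_average_epochs, cfg.epochs)
    tail_sum = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            opt.zero_grad()
            out = model.network.forward(xb, training=True)
            loss = loss_fn.forward(out, yb)
            model.network.backward(loss_fn.backward())
            opt.step()
            batch_losses.append(loss)
        if tail_k and epoch >= cfg.epochs - tail_k:
            params = [p.value for p in model.network.params() if p.trainable]
            if tail_sum is None:
                tail_sum = [p.astype(np.float64) for p in params]
            else:
                for acc, p in zip(tail_sum, params):
                    acc += p
        val_out = model.network.predict(x_val, batch_size=max(cfg.batch_size, 64))
        val_loss_fn = (nn.RMSELoss() if dataset.task == "regression"
                       else nn.SoftmaxCrossEntropy())
        val_loss = val_loss_fn.forward(val_out, y_val)
        history.train_loss.append(float(np.mean(batch_losses)))
        history.val_loss.append(float(val_loss))
        if cfg.verbose:
            print(f"epoch {epoch + 1:3d}/{cfg.epochs} "
                  f"train {history.train_loss[-1]:.4f} val {val_loss:.4f}")
    if tail_sum is not None:
        trainable = [p for p in model.network.params() if p.trainable]
        for p, acc in zip(trainable, tail_sum):
            p.value[...] = (acc / tail_k).astype(p.value.dtype)
    return history


def evaluate(model: TemporalModel, dataset: SignalDataset,
             split: str = "test") -> MetricsReport:
    """Metrics of ``model`` on one split (or the whole set if split is None)."""
    ds = dataset.subset(split) if split is not None else dataset
    pred = model.predict_dataset(ds)
    if model.spec.task == "regression":
        y = ds.rate_labels()
        values = regression_metrics(y, pred)
        values["r2_star_fc"] = r2_star(y[:, 0], pred[:, 0])
        values["r2_star_fr"] = r2_star(y[:, 1], pred[:, 1])
        return MetricsReport(kind="regression", values=values, n=len(ds))
    report = classification_metrics(ds.state_indices(), pred.argmax(axis=1),
                                    class_names=ds.class_names)
    return report


def repeated_evaluation(spec: ModelSpec, dataset: SignalDataset,
                        cfg: TrainConfig = TrainConfig(),
                        n_repeats: Optional[int] = None,
                        retrain: bool = True) -> MetricsReport:
    """Train/evaluate ``n_repeats`` times with distinct seeds; mean +/- std.

    ``retrain=False`` trains once and only repeats the (deterministic) test
    pass, mirroring a repeated-test-compilation protocol with a fixed model.
    """
    n_repeats = cfg.n_test_repeats if n_repeats is None else n_repeats
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rows: List[Dict[str, float]] = []
    model = None
    for rep in range(n_repeats):
        if retrain or model is None:
            rep_spec = replace(spec, seed=derive_seed(spec.seed, f"repeat-{rep}"))
            model = build_model(rep_spec)
            train(model, dataset, replace(cfg, seed=derive_seed(cfg.seed, f"repeat-{rep}")))
        rows.append(dict(evaluate(model, dataset, "test").values))
    frame = pd.DataFrame(rows)
    mean = frame.mean().to_dict()
    std = (frame.std(ddof=0) if n_repeats == 1 else frame.std(ddof=1)).to_dict()
    if n_repeats == 1:
        std = {k: 0.0 for k in mean}
    kind = "regression" if spec.task == "regression" else "classification"
    return MetricsReport(kind=kind, values=dict(rows[-1]), mean=mean, std=std,
                         n=len(rows))


def state_r2star_report(model: TemporalModel, generalization_set: SignalDataset
                        ) -> pd.DataFrame:
    """Per-state, per-target R2* (in percent) on the generalization subjects.

    The generalization records carry both continuous (Fc, Fr) and state
    labels; records are grouped by state and R2* computed per target.
    """
    states = np.array([r.state for r in generalization_set.records])
    if any(s is None for s in states):
        raise ValueError("generalization set must carry state labels")
    y = generalization_set.rate_labels()
    pred = model.predict_dataset(generalization_set)
    rows = {}
    for state in generalization_set.class_names:
        mask = states == state
        if not mask.any():
            rows[state] = {"fr": np.nan, "fc": np.nan}  # flagged: empty group
            continue
        rows[state] = {
            "fr": 100.0 * r2_star(y[mask, 1], pred[mask, 1]),
            "fc": 100.0 * r2_star(y[mask, 0], pred[mask, 0]),
        }
    return pd.DataFrame(rows).T[["fr", "fc"]]
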