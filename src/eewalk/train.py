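"""Model training: MSE + L2 loss, Adam, one-cycle learning-rate schedule.

The loss is the mean squared error between normalized predictions and
normalized targets plus ``l2_coeff`` times the sum of squared kernel
weights (biases excluded).  The learning rate follows a one-cycle policy:
cosine warm-up from max_lr/div_factor to max_lr over the first ``pct_start``
fraction of all optimizer steps, then cosine annealing down to
max_lr/final_div_factor.  Only the 0.001 peak and the 100-epoch budget are
fixed for the whole model family; batch size, the L2 coefficient and
the schedule shape parameters are package defaults and configurable.

Training is a pure function of (model initialization, data, config seed):
minibatch order and dropout masks come from one Generator seeded by the
config, so identical seeds reproduce identical logs bit-for-bit on a fixed
platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import _nn
from .models import ModelState
from .preprocess import ScalerParams, WindowSet, apply_scalers, fit_scalers

__all__ = ["TrainConfig", "TrainLog", "one_cycle_lr", "train_model", "mse"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for the EE regression models."""

    max_lr: float = 0.001
    epochs: int = 100
    batch_size: int = 64
    l2_coeff: float = 1e-4
    dropout: float = 0.5
    seed: int = 0
    pct_start: float = 0.3
    div_factor: float = 25.0
    final_div_factor: float = 1e4

    def __post_init__(self) -> None:
        if self.max_lr <= 0:
            raise ValueError("max_lr must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.pct_start < 1.0:
            raise ValueError("pct_start must be in (0, 1)")
        if self.l2_coeff < 0:
            raise ValueError("l2_coeff must be >= 0")


@dataclass
class TrainLog:
    """Per-epoch training diagnostics in normalized target units."""

    epoch: List[int] = field(default_factory=list)
    lr: List[float] = field(default_factory=list)
    train_mse: List[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": self.epoch, "lr": self.lr, "train_mse": self.train_mse})

    def __len__(self) -> int:
        return len(self.epoch)


def one_cycle_lr(step_fraction: float, cfg: TrainConfig) -> float:
    """Learning rate at a fractional position of the training run.

    Cosine from max_lr/div_factor up to exactly max_lr at ``pct_start``,
    then cosine down to max_lr/final_div_factor at the end.
    """
    if not 0.0 <= step_fraction <= 1.0:
        raise ValueError("step_fraction must be in [0, 1]")
    if step_fraction <= cfg.pct_start:
        p = step_fraction / cfg.pct_start
        start, end = cfg.max_lr / cfg.div_factor, cfg.max_lr
    else:
        p = (step_fraction - cfg.pct_start) / (1.0 - cfg.pct_start)
        start, end = cfg.max_lr, cfg.max_lr / cfg.final_div_factor
    return end + (start - end) * 0.5 * (1.0 + np.cos(np.pi * p))


def mse(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error; raises on length mismatch or empty input."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape or pred.size == 0:
        raise ValueError("pred and target must be non-empty arrays of equal shape")
    return float(np.mean((pred - target) ** 2))


def train_model(
    model: ModelState,
    data: WindowSet,
    cfg: TrainConfig,
    scalers: Optional[ScalerParams] = None,
) -> Tuple[ModelState, TrainLog]:
    """Train a model in place on an (unscaled) window or stride set.

    Scalers are fitted on ``data`` itself unless pre-fitted ones are passed
    (they must then come from this same training fold to avoid leakage);
    the trained model carries them for inference.  Aborts on NaN loss.
    """
    if data.scaled:
        raise ValueError("train_model expects unscaled data; scaling is internal")
    if len(data) < cfg.batch_size:
        raise ValueError(f"need at least batch_size={cfg.batch_size} samples, got {len(data)}")

    sp = scalers if scalers is not None else fit_scalers(data)
    scaled = apply_scalers(data, sp)
    x = scaled.x
    y = scaled.y_w.astype(np.float64)
    feats = scaled.subject_features

    n = len(scaled)
    n_batches = int(np.ceil(n / cfg.batch_size))
    total_steps = cfg.epochs * n_batches
    rng = np.random.default_rng(cfg.seed)
    opt = _nn.Adam(model.net)
    log = TrainLog()

    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_sse = 0.0
        lr = cfg.max_lr
        for bi in range(n_batches):
            idx = order[bi * cfg.batch_size:(bi + 1) * cfg.batch_size]
            frac = step / (total_steps - 1) if total_steps > 1 else 1.0
            lr = one_cycle_lr(frac, cfg)
            pred = model.net.forward(x[idx], feats[idx], train=True, rng=rng)
            err = pred.astype(np.float64) - y[idx]
            batch_mse = float(np.mean(err ** 2))
            if not np.isfinite(batch_mse):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch + 1}, batch {bi + 1}: "
                    "training diverged"
                )
            epoch_sse += batch_mse * len(idx)
            model.net.backward((2.0 / len(idx)) * err)
            opt.step(lr, cfg.l2_coeff)
            step += 1
        log.epoch.append(epoch + 1)
        log.lr.append(lr)
        log.train_mse.append(epoch_sse / n)

    model.scalers = sp
    return model, log
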