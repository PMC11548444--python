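"""Training loop for the heart-rate network.

Waveform regression: the network predicts the diff-normalized blood-volume
pulse per frame and is fitted by mean squared error (negative Pearson
correlation is available as an alternative).  Optimization uses AdamW
(decoupled weight decay) with a one-cycle cosine learning-rate schedule
peaking at the configured rate, gradient-norm clipping at 1.0, and the
standard small-batch regime: batch size 4, 30 epochs, peak learning rate
0.01, weight decay 9e-3, 80/20 train/validation split *by clip* so no clip
contributes chunks to both sides.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine as eng
from .network import MDARNetwork
from .preprocessing import ProcessedChunk

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "waveform_loss", "split_dataset", "train"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 4
    epochs: int = 30
    lr: float = 0.01
    weight_decay: float = 9e-3
    split: tuple[float, float] = (0.8, 0.2)
    seed: int = 0
    loss: str = "mse"  # "mse" or "neg_pearson"
    optimizer: str = "adamw"
    scheduler: str = "one_cycle"
    grad_clip: float = 1.0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.loss not in ("mse", "neg_pearson"):
            raise ValueError("loss must be 'mse' or 'neg_pearson'")
        if self.optimizer != "adamw" or self.scheduler not in ("one_cycle", "constant"):
            raise ValueError("only adamw with one_cycle/constant schedule is implemented")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_mae_bpm: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "val_mae_bpm": self.val_mae_bpm,
                "lr": self.lr,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def waveform_loss(pred: np.ndarray, label: np.ndarray) -> float:
    """Mean squared difference between predicted and reference waveforms."""
    pred = np.asarray(pred, np.float64).ravel()
    label = np.asarray(label, np.float64).ravel()
    if pred.shape != label.shape:
        raise ValueError("waveforms must have equal length")
    return float(np.mean((pred - label) ** 2))


def split_dataset(
    chunks: list[ProcessedChunk],
    split: tuple[float, float] = (0.8, 0.2),
    seed: int = 0,
) -> tuple[list[ProcessedChunk], list[ProcessedChunk]]:
    """Split chunks into train/validation by clip, never by chunk.

    Clip assignment is a seeded permutation; the training side receives
    ``ceil(train_fraction * n_clips)`` clips.
    """
    clip_ids = sorted({c.clip_id for c in chunks})
    if len(clip_ids) < 2:
        raise ValueError("need at least 2 clips to split")
    if len(clip_ids) < 5:
        logger.warning("fewer than 5 clips: validation side will be very small")
    rng = np.random.default_rng(seed)
    order = [clip_ids[i] for i in rng.permutation(len(clip_ids))]
    n_train = math.ceil(split[0] * len(order))
    train_ids = set(order[:n_train])
    train = [c for c in chunks if c.clip_id in train_ids]
    val = [c for c in chunks if c.clip_id not in train_ids]
    return train, val


def _one_cycle_lr(step: int, total: int, max_lr: float) -> float:
    """Cosine one-cycle: warm up over the first 30%, anneal over the rest."""
    pct_start, div, final_div = 0.3, 25.0, 1e4
    warm = max(1, int(pct_start * total))
    if step < warm:
        frac = step / warm
        lo = max_lr / div
        return lo + (max_lr - lo) * 0.5 * (1 - math.cos(math.pi * frac))
    frac = (step - warm) / max(1, total - warm)
    lo = max_lr / final_div
    return lo + (max_lr - lo) * 0.5 * (1 + math.cos(math.pi * frac))


class _AdamW:
    def __init__(self, params, weight_decay):
        self.params = params
        self.wd = weight_decay
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, lr: float) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.data -= lr * self.wd * p.data  # decoupled decay
            p.data -= lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _clip_grads(params, max_norm: float) -> None:
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = math.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale


def _stack(chunks: list[ProcessedChunk]):
    static = np.stack([c.static_input for c in chunks])
    dynamic = np.stack([c.dynamic_input for c in chunks])
    labels = np.stack([c.label for c in chunks])
    return static, dynamic, labels


def _eval_loss_and_mae(net, chunks, loss_name, batch_size=8):
    from .evaluation import estimate_hr

    losses, errs = [], []
    for i in range(0, len(chunks), batch_size):
        batch = chunks[i : i + batch_size]
        static, dynamic, labels = _stack(batch)
        pred = net.predict(static, dynamic)
        if loss_name == "neg_pearson":
            t = eng.neg_pearson(eng.Tensor(pred.ravel(), requires_grad=False), labels)
            losses.append(float(t.data))
        else:
            losses.append(waveform_loss(pred, labels))
        for j, c in enumerate(batch):
            if np.isfinite(c.hr_true):
                try:
                    hr = estimate_hr(pred[j], c.fps)
                    errs.append(abs(hr - c.hr_true))
                except ValueError:
                    pass
    mae = float(np.mean(errs)) if errs else float("nan")
    return float(np.mean(losses)), mae


def train(
    model: MDARNetwork,
    dataset: list[ProcessedChunk],
    config: TrainConfig = TrainConfig(),
) -> tuple[MDARNetwork, TrainHistory]:
    """Fit the network on processed chunks; returns (model, history).

    The best-validation-loss parameters are restored into the model at the
    end.  Deterministic for a fixed seed on a fixed numeric backend.
    """
    if not dataset:
        raise ValueError("empty dataset")
    train_chunks, val_chunks = split_dataset(dataset, config.split, config.seed)
    if not train_chunks or not val_chunks:
        raise ValueError("split produced an empty train or validation side")
    rng = np.random.default_rng(config.seed)
    opt = _AdamW(model.params, config.weight_decay)
    steps_per_epoch = max(1, math.ceil(len(train_chunks) / config.batch_size))
    total_steps = steps_per_epoch * config.epochs
    history = TrainHistory()
    best_val = math.inf
    best_params = None
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_chunks))
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            batch = [train_chunks[j] for j in order[i : i + config.batch_size]]
            static, dynamic, labels = _stack(batch)
            lr = (
                _one_cycle_lr(step, total_steps, config.lr)
                if config.scheduler == "one_cycle"
                else config.lr
            )
            opt.zero_grad()
            pred = model.forward(static, dynamic, training=True, rng=rng)
            if config.loss == "neg_pearson":
                loss = eng.neg_pearson(pred, labels)
            else:
                loss = eng.mse(pred, labels)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch+1}, step {step}: "
                    "training diverged (try a lower learning rate)"
                )
            loss.backward()
            _clip_grads(model.params, config.grad_clip)
            opt.step(lr)
            epoch_losses.append(float(loss.data))
            step += 1
        val_loss, val_mae = _eval_loss_and_mae(model, val_chunks, config.loss)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_mae_bpm.append(val_mae)
        history.lr.append(lr)
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: p.data.copy() for k, p in model.params.items()}
            history.best_epoch = epoch + 1
        logger.info(
            "epoch %d/%d train %.4f val %.4f val-MAE %.2f bpm",
            epoch + 1,
            config.epochs,
            history.train_loss[-1],
            val_loss,
            val_mae,
        )
    if best_params is not None:
        for k, p in model.params.items():
            p.data = best_params[k]
    return model, history
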