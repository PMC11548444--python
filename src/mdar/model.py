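"""Model/Results facade over the pipeline modules.

``MDAR`` is built from data (raw clips or preprocessed chunks) plus
configuration; ``fit()`` trains the network and returns an ``MDARResults``
carrying the fitted parameters, the training history, held-out diagnostics
and a ``summary()`` table.  Prediction, evaluation and plotting hang off the
results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import evaluate_model, summarize_hr_errors
from .network import MDARConfig, MDARNetwork, build_mdar
from .preprocessing import PreprocessConfig, ProcessedChunk, chunk_clip, preprocess_dataset
from .training import TrainConfig, TrainHistory, train

__all__ = ["MDAR", "MDARResults"]


class MDAR:
    """Dual-branch heart-rate model bound to a training dataset.

    Parameters
    ----------
    data : list of SyntheticSample or list of ProcessedChunk
        Raw clips are preprocessed with ``preprocess``; chunks are used as-is.
    config, preprocess, train_config
        Architecture, preprocessing and optimization settings.
    """

    def __init__(
        self,
        data,
        config: MDARConfig | None = None,
        preprocess: PreprocessConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        self.config = config or MDARConfig()
        self.preprocess = preprocess or PreprocessConfig(
            chunk_len=self.config.chunk_len, target_size=self.config.image_size
        )
        if self.preprocess.chunk_len != self.config.chunk_len or (
            self.preprocess.target_size != self.config.image_size
        ):
            raise ValueError("preprocess chunk_len/target_size must match the network config")
        self.train_config = train_config or TrainConfig()
        if data and isinstance(data[0], ProcessedChunk):
            self.chunks = list(data)
        else:
            self.chunks = preprocess_dataset(data, self.preprocess)
        if not self.chunks:
            raise ValueError("no usable chunks in the training data")

    @classmethod
    def from_directory(cls, data_dir, **kwargs) -> "MDAR":
        """Build from a generated dataset directory (manifest + clip files)."""
        from .synthetic import load_dataset

        return cls(load_dataset(data_dir), **kwargs)

    def fit(self, seed: int | None = None) -> "MDARResults":
        """Train the network; returns the results object."""
        tc = self.train_config
        if seed is not None:
            from dataclasses import replace

            tc = replace(tc, seed=seed)
        net = build_mdar(self.config, seed=tc.seed)
        net, history = train(net, self.chunks, tc)
        return MDARResults(model=self, network=net, history=history, train_config=tc)


@dataclass
class MDARResults:
    """Fitted network plus training diagnostics."""

    model: MDAR
    network: MDARNetwork
    history: TrainHistory
    train_config: TrainConfig
    _holdout: dict = field(default_factory=dict)

    def predict(self, sample) -> np.ndarray:
        """Stitched per-frame waveform prediction for one clip."""
        chunks = chunk_clip(sample, self.model.preprocess)
        if not chunks:
            raise ValueError("clip shorter than one chunk")
        static = np.stack([c.static_input for c in chunks])
        dynamic = np.stack([c.dynamic_input for c in chunks])
        return self.network.predict(static, dynamic).ravel()

    def evaluate(self, samples) -> pd.DataFrame:
        """Per-clip heart-rate report on held-out clips."""
        report = evaluate_model(self.network, samples, self.model.preprocess)
        if not report.empty:
            self._holdout = summarize_hr_errors(report)
        return report

    def save(self, path) -> None:
        self.network.save(path)

    def summary(self) -> str:
        """Human-readable fit summary."""
        cfg = self.model.config
        h = self.history
        lines = [
            "MDAR fit summary",
            "=" * 48,
            f"stages (widths)     : {cfg.stage_widths}",
            f"input               : {cfg.image_size}x{cfg.image_size}, chunks of {cfg.chunk_len} frames",
            f"shift fractions     : alpha1={cfg.shift.alpha1:.4g}, alpha2={cfg.shift.alpha2:.4g}",
            f"fusion beta         : {cfg.fusion.beta}",
            f"trainable parameters: {self.network.count_parameters()}",
            f"optimizer           : {self.train_config.optimizer} "
            f"(lr={self.train_config.lr}, wd={self.train_config.weight_decay}, "
            f"batch={self.train_config.batch_size})",
            f"epochs run          : {len(h.train_loss)} (best val at epoch {h.best_epoch})",
            f"final train loss    : {h.train_loss[-1]:.4f}",
            f"best val loss       : {min(h.val_loss):.4f}",
            f"val MAE at best     : {h.val_mae_bpm[h.best_epoch - 1]:.2f} bpm",
        ]
        if self._holdout:
            lines += [
                f"held-out MAE        : {self._holdout['mae_bpm']:.2f} bpm "
                f"({self._holdout['n_clips']} clips)",
                f"held-out MAPE       : {self._holdout['mape_pct']:.2f} %",
            ]
        return "\n".join(lines)

    def plot_history(self, path=None):
        """Loss curves; writes to ``path`` if given, else returns the figure."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        epochs = np.arange(1, len(self.history.train_loss) + 1)
        ax.plot(epochs, self.history.train_loss, label="train loss")
        ax.plot(epochs, self.history.val_loss, label="val loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("waveform loss")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return None
        return fig

    def plot_prediction(self, sample, path=None):
        """Predicted vs reference diff-normalized waveform for one clip."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from .preprocessing import diff_normalize_label

        pred = self.predict(sample)
        t = np.arange(pred.size) / sample.fps
        ref = diff_normalize_label(sample.bvp)[: pred.size]
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.plot(t, ref, label="reference", alpha=0.7)
        ax.plot(t, pred, label="predicted", alpha=0.7)
        ax.set_xlabel("time [s]")
        ax.set_ylabel("diff-normalized BVP")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return None
        return fig
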