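"""Heart-rate estimation and error metrics.

The predicted waveform's dominant spectral peak inside the physiologic
0.8-4.0 Hz band gives the heart rate (bpm = 60 * argmax frequency of a
Hann-windowed, zero-padded periodogram).  Accuracy is summarized by

    MAE  = (1/N) * sum_i |yhat_i - y_i|                 [bpm]
    MAPE = (100/N) * sum_i |yhat_i - y_i| / y_i          [%]

over per-clip heart rates.  The module also recomputes relative-improvement
tables, ``100 * (other - mdar) / other`` per train/test combination plus
per-method means, from published cross-dataset benchmark values that ship
with the package (one published PhysNet cell is internally inconsistent and
is flagged rather than matched).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .synthetic import HR_BAND_HZ

__all__ = [
    "HRSeries",
    "ImprovementTable",
    "estimate_hr",
    "mae",
    "mape",
    "improvement_percent",
    "build_improvement_table",
    "load_benchmark_table",
    "load_published_improvements",
    "compare_with_published",
    "evaluate_model",
]


@dataclass
class HRSeries:
    """Paired true/predicted heart rates (bpm) over test clips."""

    y: np.ndarray
    y_hat: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, np.float64)
        self.y_hat = np.asarray(self.y_hat, np.float64)
        if self.y.shape != self.y_hat.shape or self.y.ndim != 1:
            raise ValueError("y and y_hat must be equal-length 1-D arrays")
        if self.y.size == 0:
            raise ValueError("empty series")

    @property
    def n(self) -> int:
        return self.y.size


def estimate_hr(
    waveform: np.ndarray,
    fps: float,
    band_hz: tuple[float, float] = HR_BAND_HZ,
    nfft_min: int = 2048,
) -> float:
    """Heart rate (bpm) from the periodogram peak inside ``band_hz``.

    Uses a Hann window and zero-padding to at least ``nfft_min`` bins for
    sub-bpm peak resolution on short (4-30 s) windows.  Amplitude scaling of
    the waveform does not change the result.
    """
    w = np.asarray(waveform, np.float64).ravel()
    if w.size < 4 * fps:
        raise ValueError("need at least 4 seconds of waveform to estimate HR")
    if np.ptp(w) < 1e-12 or not np.all(np.isfinite(w)):
        raise ValueError("constant or non-finite waveform: heart rate undefined")
    lo, hi = band_hz
    hi = min(hi, fps / 2.0)
    if not (0 < lo < hi):
        raise ValueError(f"empty frequency band after Nyquist clipping: ({lo}, {hi})")
    nfft = max(nfft_min, int(2 ** np.ceil(np.log2(4 * w.size))))
    freqs, power = periodogram(w - w.mean(), fs=fps, window="hann", nfft=nfft)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError("no spectral bins inside the heart-rate band")
    return 60.0 * float(freqs[mask][np.argmax(power[mask])])


def mae(series: HRSeries) -> float:
    """Mean absolute error in bpm."""
    return float(np.mean(np.abs(series.y_hat - series.y)))


def mape(series: HRSeries) -> float:
    """Mean absolute percentage error (percent)."""
    if np.any(series.y <= 0):
        raise ValueError("MAPE requires strictly positive reference heart rates")
    return float(100.0 * np.mean(np.abs(series.y_hat - series.y) / series.y))


def improvement_percent(metric_other: float, metric_mdar: float) -> float:
    """Relative improvement of MDAR over another method, in percent.

    ``100 * (other - mdar) / other``: positive when MDAR has the lower error.
    """
    if metric_other <= 0:
        raise ValueError("reference metric must be positive")
    return 100.0 * (metric_other - metric_mdar) / metric_other


@dataclass
class ImprovementTable:
    """Per-combination improvements and per-method means."""

    cells: pd.DataFrame  # method, train_set, test_set, mae_improvement_pct, mape_...
    means: pd.DataFrame  # method, mae_improvement_mean_pct, mape_improvement_mean_pct

    def to_csv(self, cells_path, means_path) -> None:
        self.cells.to_csv(cells_path, index=False)
        self.means.to_csv(means_path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "cells": self.cells.to_dict(orient="records"),
            "means": self.means.to_dict(orient="records"),
        }
        pd.Series(payload).to_json(path)


def build_improvement_table(
    metric_table: pd.DataFrame, reference_method: str = "MDAR"
) -> ImprovementTable:
    """Improvements of ``reference_method`` over every other method.

    ``metric_table`` columns: method, train_set, test_set, mae, mape; the
    reference method must appear for every train/test combination used.
    Means are taken over a method's combinations (four in the packaged
    benchmark), computed unrounded.
    """
    required = {"method", "train_set", "test_set", "mae", "mape"}
    if not required.issubset(metric_table.columns):
        raise ValueError(f"metric table must have columns {sorted(required)}")
    ref = metric_table[metric_table["method"] == reference_method]
    if ref.empty:
        raise ValueError(f"metric table has no rows for {reference_method!r}")
    ref_idx = ref.set_index(["train_set", "test_set"])
    rows = []
    for _, r in metric_table[metric_table["method"] != reference_method].iterrows():
        key = (r["train_set"], r["test_set"])
        if key not in ref_idx.index:
            raise ValueError(f"no {reference_method} row for combination {key}")
        m = ref_idx.loc[key]
        rows.append(
            {
                "method": r["method"],
                "train_set": r["train_set"],
                "test_set": r["test_set"],
                "mae_improvement_pct": improvement_percent(r["mae"], m["mae"]),
                "mape_improvement_pct": improvement_percent(r["mape"], m["mape"]),
            }
        )
    cells = pd.DataFrame(rows)
    means = (
        cells.groupby("method", sort=False)[
            ["mae_improvement_pct", "mape_improvement_pct"]
        ]
        .mean()
        .reset_index()
        .rename(
            columns={
                "mae_improvement_pct": "mae_improvement_mean_pct",
                "mape_improvement_pct": "mape_improvement_mean_pct",
            }
        )
    )
    return ImprovementTable(cells=cells, means=means)


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("mdar.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_benchmark_table() -> pd.DataFrame:
    """Published cross-dataset MAE/MAPE benchmark shipped with the package."""
    return _read_packaged("cross_dataset_benchmark.csv")


def load_published_improvements() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Published improvement cells and per-method means (as printed)."""
    return (
        _read_packaged("published_improvements.csv"),
        _read_packaged("published_improvement_means.csv"),
    )


def compare_with_published(tolerance: float = 0.2) -> pd.DataFrame:
    """Recompute the improvement table and diff it against the published one.

    Returns the cell-level comparison with a ``discrepant`` flag where the
    recomputed value differs from the published one by more than
    ``tolerance`` percentage points.  The default tolerance allows for the
    published cells' mixed rounding/truncation and for their having been
    computed from unrounded internal metrics rather than the printed
    benchmark values.  One cell exceeds it: the published PhysNet MAE
    improvement for UBFC-rPPG -> MMPD recomputes to about -12.1% against its
    printed -15.9% (its per-method MAE mean inherits the offset).
    """
    table = build_improvement_table(load_benchmark_table())
    published_cells, _ = load_published_improvements()
    merged = table.cells.merge(
        published_cells,
        on=["method", "train_set", "test_set"],
        suffixes=("_recomputed", "_published"),
    )
    merged["mae_diff"] = (
        merged["mae_improvement_pct_recomputed"] - merged["mae_improvement_pct_published"]
    )
    merged["mape_diff"] = (
        merged["mape_improvement_pct_recomputed"]
        - merged["mape_improvement_pct_published"]
    )
    merged["discrepant"] = (merged["mae_diff"].abs() > tolerance) | (
        merged["mape_diff"].abs() > tolerance
    )
    return merged


def evaluate_model(model, samples, preprocess_config) -> pd.DataFrame:
    """Per-clip heart-rate predictions for a list of synthetic samples.

    Each clip is chunked, predicted in evaluation mode, the chunk waveforms
    are stitched in order, and one heart rate is estimated per clip from the
    stitched waveform.  Returns a DataFrame with clip_id, hr_true, hr_pred
    and abs_error_bpm.
    """
    from .preprocessing import chunk_clip

    rows = []
    for sample in samples:
        chunks = chunk_clip(sample, preprocess_config)
        if not chunks:
            continue
        static = np.stack([c.static_input for c in chunks])
        dynamic = np.stack([c.dynamic_input for c in chunks])
        pred = model.predict(static, dynamic).ravel()
        hr_pred = estimate_hr(pred, sample.fps)
        rows.append(
            {
                "clip_id": sample.clip_id,
                "hr_true": sample.hr_true,
                "hr_pred": hr_pred,
                "abs_error_bpm": abs(hr_pred - sample.hr_true),
            }
        )
    return pd.DataFrame(rows)


def summarize_hr_errors(report: pd.DataFrame) -> dict[str, float]:
    """MAE (bpm) and MAPE (%) summary of an :func:`evaluate_model` report."""
    series = HRSeries(report["hr_true"].to_numpy(), report["hr_pred"].to_numpy())
    return {"mae_bpm": mae(series), "mape_pct": mape(series), "n_clips": series.n}
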