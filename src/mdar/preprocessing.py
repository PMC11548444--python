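"""Turn raw clips into network inputs.

The static branch sees chunk-standardized frames (zero mean, unit variance
per channel over the chunk); the dynamic branch sees normalized first
differences, ``d(t) = (x(t+1) - x(t)) / (x(t+1) + x(t) + eps)``, scaled by
their global standard deviation.  The ratio form cancels multiplicative
illumination gain, which is why it is the standard motion representation in
end-to-end rPPG pipelines.  Labels are supervised in the same
diff-normalized space by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._engine import bilinear_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    chunk_len: int = 180
    target_size: int = 72
    epsilon: float = 1e-7
    resize_method: str = "bilinear"
    label_mode: str = "diff"  # "diff" or "raw"

    def __post_init__(self) -> None:
        if self.chunk_len < 4:
            raise ValueError("chunk_len must be >= 4")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.resize_method != "bilinear":
            raise ValueError("only bilinear resizing is implemented")
        if self.label_mode not in ("diff", "raw"):
            raise ValueError("label_mode must be 'diff' or 'raw'")


@dataclass
class ProcessedChunk:
    """Fixed-length network inputs for one chunk of one clip."""

    static_input: np.ndarray  # (T, H, W, 3) standardized
    dynamic_input: np.ndarray  # (T, H, W, 3) diff-normalized
    label: np.ndarray  # (T,)
    clip_id: str = ""
    chunk_index: int = 0
    fps: float = 30.0
    hr_true: float = float("nan")
    meta: dict = field(default_factory=dict)


def standardize_frames(video: np.ndarray, epsilon: float = 1e-7) -> np.ndarray:
    """(video - mean) / (std + eps), per channel over the whole chunk."""
    video = np.asarray(video, np.float64)
    mean = video.mean(axis=(0, 1, 2), keepdims=True)
    std = video.std(axis=(0, 1, 2), keepdims=True)
    if np.all(std < 1e-12):
        logger.warning("constant video: standardization returns zeros")
        return np.zeros_like(video)
    return (video - mean) / (std + epsilon)


def diff_normalize_frames(video: np.ndarray, epsilon: float = 1e-7) -> np.ndarray:
    """Framewise difference over framewise sum, std-scaled, zero-padded tail."""
    video = np.asarray(video, np.float64)
    if video.shape[0] < 2:
        raise ValueError("need at least two frames to difference")
    num = video[1:] - video[:-1]
    den = video[1:] + video[:-1] + epsilon
    d = num / den
    d[~np.isfinite(d)] = 0.0
    std = d.std()
    if std > 1e-12:
        d = d / std
    out = np.zeros_like(video)
    out[:-1] = d
    out[~np.isfinite(out)] = 0.0
    return out


def diff_normalize_label(bvp: np.ndarray) -> np.ndarray:
    """First difference of the pulse waveform, std-scaled, zero-padded tail."""
    bvp = np.asarray(bvp, np.float64)
    if bvp.shape[0] < 2:
        raise ValueError("need at least two samples to difference")
    d = np.diff(bvp)
    std = d.std()
    if std <= 1e-12:
        logger.warning("constant label: diff-normalization returns zeros")
        return np.zeros_like(bvp)
    out = np.zeros_like(bvp)
    out[:-1] = d / std
    return out


def resize_frames(video: np.ndarray, target_size: int) -> np.ndarray:
    """Bilinear spatial resize of a (T, H, W, C) stack to target_size^2."""
    t, h, w, c = video.shape
    if h == target_size and w == target_size:
        return np.asarray(video, np.float64)
    mh = bilinear_matrix(h, target_size)
    mw = bilinear_matrix(w, target_size)
    out = np.einsum("ih,thwc->tiwc", mh, np.asarray(video, np.float64))
    return np.einsum("jw,tiwc->tijc", mw, out)


def chunk_clip(sample, config: PreprocessConfig) -> list[ProcessedChunk]:
    """Cut a clip into non-overlapping fixed-length chunks and normalize each.

    The trailing remainder (fewer than ``chunk_len`` frames) is dropped; a
    clip shorter than one chunk yields an empty list with a warning.
    """
    video = resize_frames(sample.video, config.target_size)
    t_total = video.shape[0]
    n_chunks = t_total // config.chunk_len
    if n_chunks == 0:
        logger.warning(
            "clip %s has %d frames < chunk_len %d: no chunks produced",
            getattr(sample, "clip_id", "?"),
            t_total,
            config.chunk_len,
        )
        return []
    chunks = []
    for k in range(n_chunks):
        sl = slice(k * config.chunk_len, (k + 1) * config.chunk_len)
        seg = video[sl]
        bvp_seg = sample.bvp[sl]
        if config.label_mode == "diff":
            label = diff_normalize_label(bvp_seg)
        else:
            label = np.asarray(bvp_seg, np.float64).copy()
        chunks.append(
            ProcessedChunk(
                static_input=standardize_frames(seg, config.epsilon).astype(np.float32),
                dynamic_input=diff_normalize_frames(seg, config.epsilon).astype(np.float32),
                label=label.astype(np.float32),
                clip_id=getattr(sample, "clip_id", ""),
                chunk_index=k,
                fps=sample.fps,
                hr_true=getattr(sample, "hr_true", float("nan")),
            )
        )
    return chunks


def preprocess_dataset(samples, config: PreprocessConfig) -> list[ProcessedChunk]:
    """Chunk every clip; order is clip order, then chunk order."""
    out: list[ProcessedChunk] = []
    for s in samples:
        out.extend(chunk_clip(s, config))
    return out
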