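"""Synthetic facial-video clips with a known embedded blood-volume pulse.

Real rPPG footage couples a quasi-periodic skin-color modulation (the blood
volume pulse, BVP) with pixel noise, slow illumination drift and small head
motion.  The generator reproduces those ingredients on a skin-toned patch:

* an elliptical "face" region covering ~60% of the frame carries the pulse,
  applied chromatically (green strongest, then red, then blue);
* the pulse is a unit-variance sinusoid plus an optional second harmonic at a
  heart rate inside the physiologic 0.8-4.0 Hz band;
* confounders: per-pixel Gaussian noise, a sub-band (0.05-0.2 Hz) sinusoidal
  illumination drift, and an integer-pixel random-walk translation reflected
  at a configurable maximum excursion.

Every output is a pure function of (config, seed), so downstream stages are
testable without external datasets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HR_BAND_HZ = (0.8, 4.0)  # physiologic heart-rate band
CHANNEL_WEIGHTS = np.array([0.5, 1.0, 0.3])  # R, G, B pulse strength


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for one synthetic clip (or a dataset of clips).

    ``hr_bpm`` may be a single rate or ``None``, in which case dataset
    generation draws rates uniformly from ``hr_range_bpm``.
    """

    fps: float = 30.0
    duration_s: float = 6.0
    height: int = 72
    width: int = 72
    hr_bpm: float | None = None
    hr_range_bpm: tuple[float, float] = (60.0, 120.0)
    pulse_amplitude: float = 0.05
    harmonic_weight: float = 0.3
    noise_sigma: float = 0.02
    drift_amplitude: float = 0.05
    motion_px: int = 1
    base_color: tuple[float, float, float] = (0.78, 0.60, 0.50)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0 or self.height <= 0 or self.width <= 0:
            raise ValueError("fps, duration_s, height and width must be positive")
        if not (0 <= self.pulse_amplitude < 1 and 0 <= self.drift_amplitude < 1):
            raise ValueError("pulse_amplitude and drift_amplitude must lie in [0, 1)")
        if self.noise_sigma < 0 or self.motion_px < 0:
            raise ValueError("noise_sigma and motion_px must be non-negative")
        rates = [self.hr_bpm] if self.hr_bpm is not None else list(self.hr_range_bpm)
        for r in rates:
            f = r / 60.0
            if not (HR_BAND_HZ[0] <= f <= HR_BAND_HZ[1]):
                raise ValueError(
                    f"heart rate {r} bpm ({f:.3g} Hz) outside the "
                    f"physiologic band {HR_BAND_HZ} Hz"
                )

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass
class SyntheticSample:
    """One clip: video in [0,1], its zero-mean BVP label and true heart rate."""

    video: np.ndarray  # (T, H, W, 3) float32 in [0, 1]
    bvp: np.ndarray  # (T,) zero-mean, unit-variance
    hr_true: float  # beats per minute
    fps: float
    saturated_fraction: float = 0.0
    clip_id: str = ""
    meta: dict = field(default_factory=dict)


def generate_bvp(
    hr_bpm: float, fps: float, n_frames: int, harmonic_weight: float = 0.3
) -> np.ndarray:
    """Zero-mean, unit-variance pulse waveform at ``hr_bpm``.

    ``s(t) = sin(2*pi*f*t) + harmonic_weight * sin(4*pi*f*t + pi/3)`` with
    ``f = hr_bpm/60``, then centred and scaled to unit variance.  The second
    harmonic gives the waveform the skewed systolic shape of real PPG without
    displacing the dominant spectral peak (requires ``harmonic_weight < 1``).
    """
    f = hr_bpm / 60.0
    if not (HR_BAND_HZ[0] <= f <= HR_BAND_HZ[1]):
        raise ValueError(f"{hr_bpm} bpm is outside the physiologic band")
    if fps < 2.0 * f:
        raise ValueError(f"fps {fps} violates Nyquist for {f:.3g} Hz pulse")
    if n_frames < 2 * fps:
        raise ValueError("need at least 2 seconds of frames to resolve the pulse")
    t = np.arange(n_frames) / fps
    s = np.sin(2 * np.pi * f * t) + harmonic_weight * np.sin(4 * np.pi * f * t + np.pi / 3)
    s = s - s.mean()
    return s / s.std()


def _face_mask(height: int, width: int) -> np.ndarray:
    """Centered ellipse covering ~60% of the frame (a stand-in face ROI)."""
    a = 0.45 * width  # semi-axis along x
    b = 0.6 * height * width / (np.pi * a)  # solves pi*a*b = 0.6*H*W
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    return (((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0).astype(np.float64)


def _motion_offsets(rng: np.random.Generator, n: int, max_px: int) -> np.ndarray:
    """Integer random walk in 2-D, reflected at +/- max_px."""
    if max_px == 0:
        return np.zeros((n, 2), int)
    steps = rng.integers(-1, 2, size=(n, 2))
    pos = np.zeros((n, 2), int)
    cur = np.zeros(2, int)
    for i in range(n):
        cur = cur + steps[i]
        for k in range(2):  # reflect at the excursion limit
            if cur[k] > max_px:
                cur[k] = 2 * max_px - cur[k]
            elif cur[k] < -max_px:
                cur[k] = -2 * max_px - cur[k]
        pos[i] = cur
    return pos


def generate_clip(config: SyntheticConfig, clip_id: str = "clip") -> SyntheticSample:
    """Render one clip; bit-identical for identical (config, seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    hr = config.hr_bpm
    if hr is None:
        hr = float(rng.uniform(*config.hr_range_bpm))
    bvp = generate_bvp(hr, config.fps, n, config.harmonic_weight)

    h, w = config.height, config.width
    mask = _face_mask(h, w)
    base = np.asarray(config.base_color, np.float64)
    t_axis = np.arange(n) / config.fps

    drift = np.zeros(n)
    if config.drift_amplitude > 0:
        f_d = rng.uniform(0.05, 0.2)
        phi = rng.uniform(0, 2 * np.pi)
        drift = config.drift_amplitude * np.sin(2 * np.pi * f_d * t_axis + phi)

    offsets = _motion_offsets(rng, n, config.motion_px)

    pulse_map = mask[:, :, None] * CHANNEL_WEIGHTS[None, None, :]  # (H, W, 3)
    video = np.empty((n, h, w, 3), np.float32)
    saturated = 0
    for i in range(n):
        frame = base[None, None, :] + config.pulse_amplitude * bvp[i] * pulse_map
        if offsets[i, 0] or offsets[i, 1]:
            frame = np.roll(frame, (offsets[i, 0], offsets[i, 1]), axis=(0, 1))
        frame = frame + drift[i]
        if config.noise_sigma > 0:
            frame = frame + rng.normal(0.0, config.noise_sigma, frame.shape)
        saturated += int(((frame < 0) | (frame > 1)).sum())
        video[i] = np.clip(frame, 0.0, 1.0)

    sat_frac = saturated / video.size
    if sat_frac > 0.5:
        warnings.warn(
            f"{sat_frac:.0%} of pixels saturated; pulse signal is being clipped",
            RuntimeWarning,
            stacklevel=2,
        )
    return SyntheticSample(
        video=video,
        bvp=bvp.astype(np.float64),
        hr_true=float(hr),
        fps=config.fps,
        saturated_fraction=sat_frac,
        clip_id=clip_id,
        meta={"seed": config.seed},
    )


def generate_dataset(
    n_clips: int, config: SyntheticConfig, seed: int | None = None
) -> list[SyntheticSample]:
    """Generate ``n_clips`` clips with per-clip seeds derived from one master seed.

    Heart rates are drawn uniformly from ``config.hr_range_bpm`` unless the
    config pins ``hr_bpm``.
    """
    if n_clips < 1:
        raise ValueError("n_clips must be >= 1")
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    hr_rng = np.random.default_rng(ss.spawn(1)[0])
    clip_seeds = ss.generate_state(n_clips + 1)[1:]  # state 0 reserved for HR draws
    samples = []
    for i in range(n_clips):
        hr = config.hr_bpm
        if hr is None:
            hr = float(hr_rng.uniform(*config.hr_range_bpm))
        cfg_i = replace(config, hr_bpm=hr, seed=int(clip_seeds[i] % (2**31)))
        samples.append(generate_clip(cfg_i, clip_id=f"clip{i:04d}"))
    return samples


def save_dataset(samples: list[SyntheticSample], out_dir) -> pd.DataFrame:
    """Write one .npz per clip plus a manifest CSV; returns the manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        path = out / f"{s.clip_id}.npz"
        np.savez_compressed(
            path, video=s.video, bvp=s.bvp, hr_true=s.hr_true, fps=s.fps
        )
        rows.append(
            {
                "clip_id": s.clip_id,
                "path": path.name,
                "fps": s.fps,
                "hr_true": s.hr_true,
                "seed": s.meta.get("seed", -1),
                "saturated_fraction": s.saturated_fraction,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_dataset(data_dir) -> list[SyntheticSample]:
    """Read clips back from a directory written by :func:`save_dataset`."""
    from pathlib import Path

    data = Path(data_dir)
    manifest = pd.read_csv(data / "manifest.csv")
    samples = []
    for _, row in manifest.iterrows():
        with np.load(data / row["path"]) as z:
            samples.append(
                SyntheticSample(
                    video=z["video"],
                    bvp=z["bvp"],
                    hr_true=float(z["hr_true"]),
                    fps=float(z["fps"]),
                    saturated_fraction=float(row.get("saturated_fraction", 0.0)),
                    clip_id=str(row["clip_id"]),
                    meta={"seed": int(row.get("seed", -1))},
                )
            )
    return samples


def export_png_frames(sample: SyntheticSample, out_dir) -> None:
    """Write a clip as PNG frames plus a plain-text waveform file."""
    from pathlib import Path

    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(sample.video):
        iio.imwrite(out / f"frame{i:05d}.png", (frame * 255).astype(np.uint8))
    np.savetxt(out / "bvp.txt", sample.bvp, header=f"hr_true={sample.hr_true} fps={sample.fps}")
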