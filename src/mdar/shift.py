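"""Temporal shift operators for video feature tensors.

A temporal shift module (TSM) injects temporal context into per-frame 2-D
convolutions by moving a fraction of the channels one frame along the time
axis.  The alternating time-shift module (ATSM) extends this with a second,
smaller channel fraction shifted by two frames in each direction, widening
the temporal receptive field at zero parameter cost.

All operators work on 5-axis feature blocks laid out ``(n, c, t, h, w)``
(batch, channel, time, height, width).  Vacated frames are filled with a
constant (zero by default); there is no wrap-around.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ShiftConfig", "partition_channels", "tsm_shift", "atsm_shift"]


@dataclass(frozen=True)
class ShiftConfig:
    """Channel partition fractions for the alternating time-shift.

    Parameters
    ----------
    alpha1 : float
        Fraction of channels shifted by one frame in each direction.
    alpha2 : float
        Fraction of channels shifted by two frames in each direction.
    fill_value : float
        Constant written into frames vacated by the shift.
    """

    alpha1: float = 1 / 4
    alpha2: float = 1 / 12
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("shift fractions must be non-negative")
        if 2 * self.alpha1 + 2 * self.alpha2 > 1 + 1e-12:
            raise ValueError(
                "2*alpha1 + 2*alpha2 must not exceed 1 "
                f"(got alpha1={self.alpha1}, alpha2={self.alpha2})"
            )


def partition_channels(
    n_channels: int, alpha1: float, alpha2: float
) -> list[tuple[int, int]]:
    """Partition ``[0, C)`` into the five contiguous shift segments.

    Segment sizes are ``floor(alpha1*C)`` for each single-frame direction and
    ``floor(alpha2*C)`` for each double-frame direction; remainder channels
    are assigned to the unchanged segment.  Returns five ``(start, stop)``
    ranges ordered as (back-1, forward-1, back-2, forward-2, unchanged).
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if alpha1 < 0 or alpha2 < 0 or 2 * alpha1 + 2 * alpha2 > 1 + 1e-12:
        raise ValueError("invalid shift fractions")
    k1 = int(np.floor(alpha1 * n_channels))
    k2 = int(np.floor(alpha2 * n_channels))
    bounds = [0, k1, 2 * k1, 2 * k1 + k2, 2 * k1 + 2 * k2, n_channels]
    return [(bounds[i], bounds[i + 1]) for i in range(5)]


# out[t] = in[t + s]: s > 0 moves future frames backward into slot t,
# s < 0 moves past frames forward.
_ATSM_SHIFTS = (1, -1, 2, -2, 0)


def _shift_segments(
    x: np.ndarray,
    segments: list[tuple[int, int]],
    shifts: tuple[int, ...],
    fill_value: float,
) -> np.ndarray:
    n, c, t, h, w = x.shape
    out = np.empty_like(x)
    for (c0, c1), s in zip(segments, shifts):
        if c1 <= c0:
            continue
        if s == 0:
            out[:, c0:c1] = x[:, c0:c1]
            continue
        out[:, c0:c1] = fill_value
        m = abs(s)
        if m >= t:
            continue  # every frame vacated
        if s > 0:
            out[:, c0:c1, : t - m] = x[:, c0:c1, m:]
        else:
            out[:, c0:c1, m:] = x[:, c0:c1, : t - m]
    return out


def _check_block(x: np.ndarray) -> None:
    if x.ndim != 5:
        raise ValueError(f"expected a 5-axis (n,c,t,h,w) tensor, got ndim={x.ndim}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature block contains non-finite values")


def tsm_shift(x: np.ndarray, alpha1: float, fill_value: float = 0.0) -> np.ndarray:
    """Single-frame temporal shift of channel fractions (classic TSM).

    The first ``floor(alpha1*C)`` channels take their value from the next
    frame (``out[t] = in[t+1]``), the second such segment from the previous
    frame, and the rest are copied unchanged.  Vacated frames are filled with
    ``fill_value``.
    """
    _check_block(x)
    if alpha1 < 0 or alpha1 > 0.5:
        raise ValueError("alpha1 must lie in [0, 1/2]")
    segments = partition_channels(x.shape[1], alpha1, 0.0)
    return _shift_segments(x, segments, _ATSM_SHIFTS, fill_value)


def atsm_shift(x: np.ndarray, config: ShiftConfig) -> np.ndarray:
    """Alternating single/double-frame temporal shift (ATSM).

    Channel segments, in order: ``floor(alpha1*C)`` channels shifted backward
    by one frame (``out[t]=in[t+1]``), the same number forward by one frame,
    ``floor(alpha2*C)`` backward by two frames, the same number forward by two
    frames, and the remainder unchanged.  With ``alpha2=0`` this reduces
    exactly to :func:`tsm_shift`.
    """
    _check_block(x)
    segments = partition_channels(x.shape[1], config.alpha1, config.alpha2)
    return _shift_segments(x, segments, _ATSM_SHIFTS, config.fill_value)
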