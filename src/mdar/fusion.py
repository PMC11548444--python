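"""Dynamic-static feature fusion (DSFFM) and multiscale feature fusion.

DSFFM turns the static (appearance) branch into a multiplicative gate on the
dynamic (motion) branch: a 1x1 convolution followed by SiLU produces a gate
map from the static features, the map is normalized by its per-sample mean
magnitude (reducing it to an O(1) modulation), and the result is multiplied
elementwise into the dynamic features and scaled by ``beta``.  Because the
gate depends only on the static features, the fusion is exactly linear in
the dynamic branch and in ``beta``.

Multiscale fusion merges the dynamic branch's shallow (d2), intermediate
(d5) and deep (d6) feature maps: the first two are bilinearly resized to
twice the spatial size of d6, average-pooled 2x2 down to d6's size, and the
three blocks are concatenated along the channel axis.

Operators here are pure numpy functions over ``(n, c, t, h, w)`` blocks and
serve as the reference semantics; the trainable network re-implements them
on the autodiff engine and is tested against these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._engine import bilinear_matrix

__all__ = ["FusionConfig", "dsffm", "multiscale_fuse"]


@dataclass(frozen=True)
class FusionConfig:
    """``beta`` scales the fused product; 0.2 is the tuned default."""

    beta: float = 0.2
    epsilon: float = 1e-7
    conv_kernel: int = 1

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.conv_kernel != 1:
            raise ValueError("the gating convolution has kernel size 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def dsffm(
    r_n: np.ndarray,
    d_n: np.ndarray,
    weight: np.ndarray,
    bias: np.ndarray,
    config: FusionConfig = FusionConfig(),
) -> np.ndarray:
    """Gate dynamic features by normalized SiLU(conv1x1(static features)).

    ``r_n`` may carry a singleton time axis (a per-chunk appearance summary);
    the gate then broadcasts over the dynamic block's time axis.
    """
    r_n = np.asarray(r_n, np.float64)
    d_n = np.asarray(d_n, np.float64)
    if r_n.ndim != 5 or d_n.ndim != 5:
        raise ValueError("expected 5-axis (n,c,t,h,w) blocks")
    n, c, t_r, h, w = r_n.shape
    if d_n.shape[0] != n or d_n.shape[1] != c or d_n.shape[3:] != (h, w):
        raise ValueError(f"branch shape mismatch: {r_n.shape} vs {d_n.shape}")
    if t_r not in (1, d_n.shape[2]):
        raise ValueError("static time axis must be 1 or match the dynamic block")
    weight = np.asarray(weight, np.float64)
    bias = np.asarray(bias, np.float64)
    if weight.shape != (c, c) or bias.shape != (c,):
        raise ValueError("gating convolution parameters have wrong shapes")

    g = _silu(np.einsum("oc,ncthw->nothw", weight, r_n) + bias[None, :, None, None, None])
    m = np.abs(g).mean(axis=(1, 2, 3, 4))  # per-sample scalar
    a = g / (m[:, None, None, None, None] + config.epsilon)
    return a * d_n * config.beta


def _resize_block(x: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bilinear resize of the spatial axes of (n,c,t,h,w)."""
    mh = bilinear_matrix(x.shape[3], out_h)
    mw = bilinear_matrix(x.shape[4], out_w)
    y = np.einsum("ih,ncthw->nctiw", mh, x)
    return np.einsum("jw,nctiw->nctij", mw, y)


def _avgpool_block(x: np.ndarray) -> np.ndarray:
    n, c, t, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("average pooling needs even spatial sizes")
    return x.reshape(n, c, t, h // 2, 2, w // 2, 2).mean(axis=(4, 6))


def multiscale_fuse(d2: np.ndarray, d5: np.ndarray, d6: np.ndarray) -> np.ndarray:
    """Downsample d2 and d5 to d6's spatial size and concatenate channels.

    Each of d2 and d5 is bilinearly interpolated to twice d6's spatial size
    and then 2x2 average-pooled; output channels = C(d2)+C(d5)+C(d6).
    """
    blocks = [np.asarray(b, np.float64) for b in (d2, d5, d6)]
    for b in blocks:
        if b.ndim != 5:
            raise ValueError("expected 5-axis (n,c,t,h,w) blocks")
    n, _, t = blocks[2].shape[:3]
    for b in blocks[:2]:
        if b.shape[0] != n or b.shape[2] != t:
            raise ValueError("batch/time axes must match across scales")
        if b.shape[3] < blocks[2].shape[3] or b.shape[4] < blocks[2].shape[4]:
            raise ValueError("expected spatial sizes d2 >= d5 >= d6")
    h6, w6 = blocks[2].shape[3:]
    down = [
        _avgpool_block(_resize_block(b, 2 * h6, 2 * w6)) for b in blocks[:2]
    ]
    return np.concatenate(down + [blocks[2]], axis=1)
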