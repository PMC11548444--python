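"""Numba kernels for the 3x3 convolution (the training-time hot spot).

Direct convolution over a channel-first (C, B, H, W) layout: one pass over
memory, no im2col inflation.  The backward pass to the input reuses the
forward kernel with the spatially flipped, transposed weights; the weight
gradient has its own reduction kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def conv3x3_fwd(xp, w, b, y):  # pragma: no cover - exercised via _engine
    """y[co,b,i,j] = bias + sum_{ci,di,dj} w[co,ci,di,dj] * xp[ci,b,i+di,j+dj]."""
    cin, nb, hp, wp = xp.shape
    cout = w.shape[0]
    h, wd = hp - 2, wp - 2
    acc = np.empty((cout, wd), np.float32)
    for bb in range(nb):
        for i in range(h):
            for co in range(cout):
                for j in range(wd):
                    acc[co, j] = b[co]
            for ci in range(cin):
                x0 = xp[ci, bb, i]
                x1 = xp[ci, bb, i + 1]
                x2 = xp[ci, bb, i + 2]
                for co in range(cout):
                    a = acc[co]
                    w00 = w[co, ci, 0, 0]
                    w01 = w[co, ci, 0, 1]
                    w02 = w[co, ci, 0, 2]
                    w10 = w[co, ci, 1, 0]
                    w11 = w[co, ci, 1, 1]
                    w12 = w[co, ci, 1, 2]
                    w20 = w[co, ci, 2, 0]
                    w21 = w[co, ci, 2, 1]
                    w22 = w[co, ci, 2, 2]
                    for j in range(wd):
                        a[j] += (
                            w00 * x0[j]
                            + w01 * x0[j + 1]
                            + w02 * x0[j + 2]
                            + w10 * x1[j]
                            + w11 * x1[j + 1]
                            + w12 * x1[j + 2]
                            + w20 * x2[j]
                            + w21 * x2[j + 1]
                            + w22 * x2[j + 2]
                        )
            for co in range(cout):
                for j in range(wd):
                    y[co, bb, i, j] = acc[co, j]


@njit(cache=True, fastmath=True)
def conv3x3_gw(xp, g, gw):  # pragma: no cover - exercised via _engine
    """gw[co,ci,di,dj] = sum_{b,i,j} g[co,b,i,j] * xp[ci,b,i+di,j+dj]."""
    cin, nb, hp, wp = xp.shape
    cout = g.shape[0]
    h, wd = hp - 2, wp - 2
    for bb in range(nb):
        for i in range(h):
            for ci in range(cin):
                x0 = xp[ci, bb, i]
                x1 = xp[ci, bb, i + 1]
                x2 = xp[ci, bb, i + 2]
                for co in range(cout):
                    grow = g[co, bb, i]
                    s00 = np.float32(0.0)
                    s01 = np.float32(0.0)
                    s02 = np.float32(0.0)
                    s10 = np.float32(0.0)
                    s11 = np.float32(0.0)
                    s12 = np.float32(0.0)
                    s20 = np.float32(0.0)
                    s21 = np.float32(0.0)
                    s22 = np.float32(0.0)
                    for j in range(wd):
                        gv = grow[j]
                        s00 += gv * x0[j]
                        s01 += gv * x0[j + 1]
                        s02 += gv * x0[j + 2]
                        s10 += gv * x1[j]
                        s11 += gv * x1[j + 1]
                        s12 += gv * x1[j + 2]
                        s20 += gv * x2[j]
                        s21 += gv * x2[j + 1]
                        s22 += gv * x2[j + 2]
                    gw[co, ci, 0, 0] += s00
                    gw[co, ci, 0, 1] += s01
                    gw[co, ci, 0, 2] += s02
                    gw[co, ci, 1, 0] += s10
                    gw[co, ci, 1, 1] += s11
                    gw[co, ci, 1, 2] += s12
                    gw[co, ci, 2, 0] += s20
                    gw[co, ci, 2, 1] += s21
                    gw[co, ci, 2, 2] += s22
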