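"""Minimal reverse-mode automatic differentiation for the network stack.

Feature maps are stored channel-first as ``(C, B, H, W)`` float32 arrays,
where ``B`` flattens batch and time (``B = N*T``); this keeps the 3x3
convolution an im2col + single-GEMM operation, which is where essentially all
of the training time goes.  Each op returns a :class:`Tensor` carrying a
backward closure; :meth:`Tensor.backward` runs the tape in reverse
topological order.

Only the operations the heart-rate network needs are implemented.  Gradients
are verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from .shift import partition_channels, _ATSM_SHIFTS

__all__ = ["Tensor"]


class Tensor:
    """A float32 array plus the closure that back-propagates into its parents."""

    __slots__ = ("data", "grad", "_parents", "_bw", "requires_grad")

    def __init__(self, data, parents=(), bw=None, requires_grad=True):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = parents
        self._bw = bw
        # op outputs need gradients iff some parent does
        self.requires_grad = (
            any(p.requires_grad for p in parents) if parents else requires_grad
        )

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)
            if node._bw is not None:
                node.grad = None  # free intermediate gradients


def _acc(t: Tensor, g: np.ndarray) -> None:
    # Takes ownership of g (ops always pass freshly computed arrays or views
    # that stay valid); accumulation is out-of-place since g may be read-only.
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g if g.dtype == np.float32 else g.astype(np.float32)
    else:
        t.grad = t.grad + g


def conv3x3(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding 3x3 convolution. ``w``: (Cout, Cin, 3, 3), ``b``: (Cout,)."""
    from ._kernels import conv3x3_fwd, conv3x3_gw

    cin, nb, h, wd = x.data.shape
    cout = w.data.shape[0]
    xp = np.zeros((cin, nb, h + 2, wd + 2), np.float32)
    xp[:, :, 1:-1, 1:-1] = x.data
    y = np.empty((cout, nb, h, wd), np.float32)
    conv3x3_fwd(xp, w.data, b.data, y)
    out = Tensor(y, (x, w, b))

    def bw(g):
        g = np.ascontiguousarray(g, np.float32)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            conv3x3_gw(xp, g, gw)
            _acc(w, gw)
        if b.requires_grad:
            _acc(b, g.sum(axis=(1, 2, 3)))
        if x.requires_grad:
            # grad-to-input is a 3x3 convolution of the zero-padded output
            # gradient with the spatially flipped, transposed kernel
            gyp = np.zeros((cout, nb, h + 2, wd + 2), np.float32)
            gyp[:, :, 1:-1, 1:-1] = g
            w2 = np.ascontiguousarray(w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
            gx = np.empty((cin, nb, h, wd), np.float32)
            conv3x3_fwd(gyp, w2, np.zeros(cin, np.float32), gx)
            _acc(x, gx)

    out._bw = bw
    return out


def conv1x1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Pointwise convolution. ``w``: (Cout, Cin), ``b``: (Cout,)."""
    cin, nb, h, wd = x.data.shape
    x2 = x.data.reshape(cin, -1)
    y2 = w.data @ x2
    y2 += b.data[:, None]
    out = Tensor(y2.reshape(-1, nb, h, wd), (x, w, b))

    def bw(g):
        g2 = g.reshape(g.shape[0], -1)
        if w.requires_grad:
            _acc(w, g2 @ x2.T)
        if b.requires_grad:
            _acc(b, g2.sum(axis=1))
        if x.requires_grad:
            _acc(x, (w.data.T @ g2).reshape(x.data.shape))

    out._bw = bw
    return out


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, (x,))
    out._bw = lambda g: _acc(x, g * (1.0 - y * y))
    return out


def silu(x: Tensor) -> Tensor:
    sig = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(x.data * sig, (x,))
    out._bw = lambda g: _acc(x, g * sig * (1.0 + x.data * (1.0 - sig)))
    return out


def avgpool2(x: Tensor) -> Tensor:
    c, nb, h, wd = x.data.shape
    if h % 2 or wd % 2:
        raise ValueError(f"avgpool2 needs even spatial sizes, got {h}x{wd}")
    v = x.data
    y = v[:, :, 0::2, 0::2] + v[:, :, 0::2, 1::2] + v[:, :, 1::2, 0::2] + v[:, :, 1::2, 1::2]
    y *= 0.25
    out = Tensor(y, (x,))

    def bw(g):
        if not x.requires_grad:
            return
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3)
        gx *= 0.25
        _acc(x, gx)

    out._bw = bw
    return out


def temporal_shift(x: Tensor, n: int, t: int, alpha1: float, alpha2: float) -> Tensor:
    """ATSM on a (C, N*T, H, W) block; zero fill, no wrap-around."""
    c, nb, h, wd = x.data.shape
    if nb != n * t:
        raise ValueError("B axis must equal N*T")
    segments = partition_channels(c, alpha1, alpha2)
    x5 = x.data.reshape(c, n, t, h, wd)
    y5 = np.empty_like(x5)
    for (c0, c1), s in zip(segments, _ATSM_SHIFTS):
        if c1 <= c0:
            continue
        if s == 0:
            y5[c0:c1] = x5[c0:c1]
            continue
        y5[c0:c1] = 0.0
        m = abs(s)
        if m >= t:
            continue
        if s > 0:
            y5[c0:c1, :, : t - m] = x5[c0:c1, :, m:]
        else:
            y5[c0:c1, :, m:] = x5[c0:c1, :, : t - m]
    out = Tensor(y5.reshape(c, nb, h, wd), (x,))

    def bw(g):
        if not x.requires_grad:
            return
        g5 = g.reshape(c, n, t, h, wd)
        gx = np.zeros_like(g5)
        for (c0, c1), s in zip(segments, _ATSM_SHIFTS):
            if c1 <= c0:
                continue
            if s == 0:
                gx[c0:c1] = g5[c0:c1]
                continue
            m = abs(s)
            if m >= t:
                continue
            if s > 0:  # out[t'] = in[t'+s]  =>  gin[t'+s] += gout[t']
                gx[c0:c1, :, m:] = g5[c0:c1, :, : t - m]
            else:
                gx[c0:c1, :, : t - m] = g5[c0:c1, :, m:]
        _acc(x, gx.reshape(c, nb, h, wd))

    out._bw = bw
    return out


def sample_norm(x: Tensor, eps: float) -> Tensor:
    """Divide by the per-sample mean absolute value over (C, H, W)."""
    c, n, h, wd = x.data.shape
    k = c * h * wd
    m = np.abs(x.data).mean(axis=(0, 2, 3))  # (N,)
    denom = (m + eps)[None, :, None, None]
    out = Tensor(x.data / denom, (x,))

    def bw(g):
        dot = (g * x.data).sum(axis=(0, 2, 3))[None, :, None, None]
        gx = g / denom - np.sign(x.data) * dot / (k * denom * denom)
        _acc(x, gx)

    out._bw = bw
    return out


def gate_mul(d: Tensor, a: Tensor, n: int, t: int, beta: float) -> Tensor:
    """Broadcast a per-chunk gate (C, N, H, W) over time into (C, N*T, H, W)."""
    c, nb, h, wd = d.data.shape
    if a.data.shape != (c, n, h, wd) or nb != n * t:
        raise ValueError("gate/feature shape mismatch")
    d5 = d.data.reshape(c, n, t, h, wd)
    out = Tensor((d5 * a.data[:, :, None]).reshape(c, nb, h, wd) * beta, (d, a))

    def bw(g):
        g5 = g.reshape(c, n, t, h, wd)
        if d.requires_grad:
            _acc(d, (g5 * a.data[:, :, None]).reshape(c, nb, h, wd) * beta)
        if a.requires_grad:
            _acc(a, (g5 * d5).sum(axis=2) * beta)

    out._bw = bw
    return out


def resize_hw(x: Tensor, mh: np.ndarray, mw: np.ndarray) -> Tensor:
    """Separable linear resize: ``y = mh @ x @ mw.T`` applied per (C, B) slice."""
    y = np.matmul(x.data, mw.T.astype(np.float32))
    y = np.matmul(y.transpose(0, 1, 3, 2), mh.T.astype(np.float32)).transpose(0, 1, 3, 2)
    out = Tensor(y, (x,))

    def bw(g):
        gx = np.matmul(g.transpose(0, 1, 3, 2), mh.astype(np.float32)).transpose(0, 1, 3, 2)
        gx = np.matmul(gx, mw.astype(np.float32))
        _acc(x, gx)

    out._bw = bw
    return out


def concat_channels(parts: list[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([p.data for p in parts], axis=0), tuple(parts))
    sizes = [p.data.shape[0] for p in parts]

    def bw(g):
        at = 0
        for p, s in zip(parts, sizes):
            _acc(p, g[at : at + s])
            at += s

    out._bw = bw
    return out


def spatial_mean(x: Tensor) -> Tensor:
    c, nb, h, wd = x.data.shape
    out = Tensor(x.data.mean(axis=(2, 3)), (x,))

    def bw(g):
        _acc(x, np.broadcast_to(g[:, :, None, None] / (h * wd), x.data.shape))

    out._bw = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)
    out = Tensor(x.data * mask, (x,))
    out._bw = lambda g: _acc(x, g * mask)
    return out


def dense_scalar(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Map per-frame pooled features (C, B) to one scalar per frame (B,)."""
    y = x.data.T @ w.data + b.data
    out = Tensor(y, (x, w, b))

    def bw(g):
        if w.requires_grad:
            _acc(w, x.data @ g)
        if b.requires_grad:
            _acc(b, np.array(g.sum(), np.float32))
        if x.requires_grad:
            _acc(x, np.outer(w.data, g))

    out._bw = bw
    return out


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - np.asarray(target, np.float32).ravel()
    out = Tensor(np.array((diff * diff).mean(), np.float32), (pred,))
    out._bw = lambda g: _acc(pred, (2.0 / diff.size) * float(g) * diff)
    return out


def neg_pearson(pred: Tensor, target: np.ndarray) -> Tensor:
    """1 - Pearson correlation, averaged over rows of a (N, T) layout."""
    tgt = np.asarray(target, np.float32)
    n, t = tgt.shape
    p = pred.data.reshape(n, t)
    pc = p - p.mean(axis=1, keepdims=True)
    yc = tgt - tgt.mean(axis=1, keepdims=True)
    sp = np.sqrt((pc * pc).sum(axis=1)) + 1e-8
    sy = np.sqrt((yc * yc).sum(axis=1)) + 1e-8
    r = (pc * yc).sum(axis=1) / (sp * sy)
    out = Tensor(np.array((1.0 - r).mean(), np.float32), (pred,))

    def bw(g):
        # d(1-r)/dp = -(yc/(sp*sy) - r*pc/sp^2), centred term already handled
        gp = -(yc / (sp * sy)[:, None] - (r / (sp * sp))[:, None] * pc)
        gp -= gp.mean(axis=1, keepdims=True)  # gradient of the centring
        _acc(pred, (float(g) / n) * gp.reshape(pred.data.shape))

    out._bw = bw
    return out


def bilinear_matrix(src: int, dst: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (dst, src), half-pixel centres."""
    m = np.zeros((dst, src), np.float64)
    if src == dst:
        return np.eye(src)
    for i in range(dst):
        s = (i + 0.5) * src / dst - 0.5
        s = min(max(s, 0.0), src - 1.0)
        lo = int(np.floor(s))
        hi = min(lo + 1, src - 1)
        frac = s - lo
        m[i, lo] += 1.0 - frac
        m[i, hi] += frac
    return m
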