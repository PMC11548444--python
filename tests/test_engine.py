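"""Gradient correctness of the autodiff core.

Each op's backward pass is checked against central finite differences of a
float64 re-evaluation (single-element probes for smooth ops, an independent
closed-form reference where |x| kinks make finite differences unreliable).
"""

import numpy as np
import pytest

from mdar import _engine as eng
from mdar._engine import Tensor


def weighted_loss(out, wsum):
    """Scalar probe: sum(out * wsum), backprop seeds the graph with wsum."""
    t = Tensor(np.array((out.data * wsum).sum(), np.float32), (out,))
    t._bw = lambda g: eng._acc(out, float(g) * wsum.astype(np.float32))
    return t


def fd_gradients(build, arrays, wsum, h=1e-3):
    """Finite-difference gradient of sum(build(arrays)*wsum) wrt each array."""
    grads = [np.zeros_like(a, dtype=np.float64) for a in arrays]
    rng = np.random.default_rng(0)
    for k, a in enumerate(arrays):
        flat = a.ravel()
        idxs = rng.choice(flat.size, size=min(8, flat.size), replace=False)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + h
            lp = float((build(*arrays).data.astype(np.float64) * wsum).sum())
            flat[i] = orig - h
            lm = float((build(*arrays).data.astype(np.float64) * wsum).sum())
            flat[i] = orig
            grads[k].ravel()[i] = (lp - lm) / (2 * h)
    return grads, [np.abs(g) > 0 for g in grads]


def check_op(build, arrays, tol=5e-3):
    tensors = [Tensor(a.copy()) for a in arrays]
    out = build(*tensors)
    rng = np.random.default_rng(1)
    wsum = rng.standard_normal(out.data.shape)
    weighted_loss(out, wsum).backward()
    fd, masks = fd_gradients(lambda *xs: build(*[Tensor(x) for x in xs]), arrays, wsum)
    for t, g_fd, m in zip(tensors, fd, masks):
        an = t.grad if t.grad is not None else np.zeros_like(g_fd)
        diff = np.abs(np.asarray(an, np.float64) - g_fd)[m]
        scale = np.maximum(np.abs(g_fd[m]), 1.0)
        assert diff.size == 0 or np.max(diff / scale) < tol


@pytest.fixture
def arrays(rng):
    return rng.standard_normal((5, 4, 6, 6)).astype(np.float32)


class TestOpGradients:
    def test_conv3x3(self, rng, arrays):
        w = (rng.standard_normal((7, 5, 3, 3)) * 0.3).astype(np.float32)
        b = (rng.standard_normal(7) * 0.1).astype(np.float32)
        check_op(eng.conv3x3, [arrays, w, b])

    def test_conv1x1(self, rng, arrays):
        w = (rng.standard_normal((7, 5)) * 0.3).astype(np.float32)
        b = (rng.standard_normal(7) * 0.1).astype(np.float32)
        check_op(eng.conv1x1, [arrays, w, b])

    def test_tanh(self, arrays):
        check_op(eng.tanh, [arrays])

    def test_silu(self, arrays):
        check_op(eng.silu, [arrays])

    def test_avgpool2(self, arrays):
        check_op(eng.avgpool2, [arrays])

    def test_temporal_shift(self, arrays):
        check_op(lambda x: eng.temporal_shift(x, 2, 2, 0.25, 1 / 12), [arrays])

    def test_gate_mul(self, rng, arrays):
        a = rng.standard_normal((5, 2, 6, 6)).astype(np.float32)
        check_op(lambda d, g: eng.gate_mul(d, g, 2, 2, 0.2), [arrays, a])

    def test_resize(self, arrays):
        mh = eng.bilinear_matrix(6, 4)
        mw = eng.bilinear_matrix(6, 10)
        check_op(lambda x: eng.resize_hw(x, mh, mw), [arrays])

    def test_concat(self, arrays):
        check_op(lambda p, q: eng.concat_channels([p, q]), [arrays, arrays * 0.5])

    def test_spatial_mean(self, arrays):
        check_op(eng.spatial_mean, [arrays])

    def test_dense_scalar(self, rng):
        x = rng.standard_normal((5, 8)).astype(np.float32)
        w = rng.standard_normal(5).astype(np.float32)
        b = np.array(0.2, np.float32)
        check_op(eng.dense_scalar, [x, w, b])

    def test_mse(self, rng):
        pred = rng.standard_normal(12).astype(np.float32)
        tgt = rng.standard_normal((3, 4)).astype(np.float32)
        check_op(lambda p: eng.mse(p, tgt), [pred])

    def test_neg_pearson(self, rng):
        pred = rng.standard_normal(12).astype(np.float32)
        tgt = rng.standard_normal((3, 4)).astype(np.float32)
        check_op(lambda p: eng.neg_pearson(p, tgt), [pred], tol=1e-2)

    def test_sample_norm_against_closed_form(self, rng):
        # |x| kinks make FD unreliable; compare to a float64 analytic reference
        x = rng.standard_normal((5, 4, 6, 6))
        x += np.sign(x) * 0.5
        g_up = rng.standard_normal(x.shape)
        t = Tensor(x.astype(np.float32))
        out = eng.sample_norm(t, 1e-7)
        weighted_loss(out, g_up).backward()
        k = 5 * 6 * 6
        m = np.abs(x).mean(axis=(0, 2, 3))
        denom = (m + 1e-7)[None, :, None, None]
        dot = (g_up * x).sum(axis=(0, 2, 3))[None, :, None, None]
        ref = g_up / denom - np.sign(x) * dot / (k * denom**2)
        np.testing.assert_allclose(t.grad, ref, rtol=2e-4, atol=1e-5)


class TestEngineSemantics:
    def test_conv_matches_brute_force(self, rng):
        x = rng.standard_normal((3, 2, 5, 5)).astype(np.float32)
        w = rng.standard_normal((4, 3, 3, 3)).astype(np.float32)
        b = rng.standard_normal(4).astype(np.float32)
        y = eng.conv3x3(Tensor(x), Tensor(w), Tensor(b)).data
        xp = np.zeros((3, 2, 7, 7))
        xp[:, :, 1:-1, 1:-1] = x
        ref = np.zeros_like(y, dtype=np.float64)
        for co in range(4):
            ref[co] = b[co]
            for ci in range(3):
                for di in range(3):
                    for dj in range(3):
                        ref[co] += w[co, ci, di, dj] * xp[ci, :, di : di + 5, dj : dj + 5]
        np.testing.assert_allclose(y, ref, rtol=1e-5, atol=1e-5)

    def test_dropout_eval_passthrough(self, rng, arrays):
        t = Tensor(arrays)
        assert eng.dropout(t, 0.5, rng, training=False) is t

    def test_dropout_train_scales_mask(self, arrays):
        rng = np.random.default_rng(3)
        out = eng.dropout(Tensor(arrays), 0.5, rng, training=True)
        kept = out.data != 0
        np.testing.assert_allclose(out.data[kept], (arrays * 2.0)[kept], rtol=1e-6)

    def test_bilinear_matrix_partition_of_unity(self):
        m = eng.bilinear_matrix(36, 18)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_gradient_accumulates_over_consumers(self, rng):
        x = Tensor(rng.standard_normal((2, 2, 2, 2)).astype(np.float32))
        y = eng.concat_channels([eng.tanh(x), eng.silu(x)])
        weighted_loss(y, np.ones(y.data.shape)).backward()
        d = x.data.astype(np.float64)
        sig = 1 / (1 + np.exp(-d))
        ref = (1 - np.tanh(d) ** 2) + sig * (1 + d * (1 - sig))
        np.testing.assert_allclose(x.grad, ref, rtol=1e-5, atol=1e-6)
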