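"""Assembled network: shapes, determinism, information flow, checkpoints."""

import numpy as np
import pytest

from mdar import MDARConfig, build_mdar
from mdar.fusion import FusionConfig
from mdar.shift import ShiftConfig


@pytest.fixture
def net(tiny_net_config):
    return build_mdar(tiny_net_config, seed=0)


@pytest.fixture
def inputs(rng, tiny_net_config):
    shape = (2, tiny_net_config.chunk_len, 16, 16, 3)
    return (
        rng.standard_normal(shape).astype(np.float32),
        (rng.standard_normal(shape) * 0.2).astype(np.float32),
    )


class TestForward:
    def test_waveform_shape(self, net, inputs):
        s, d = inputs
        out = net.predict(s, d)
        assert out.shape == (2, 60)
        assert np.all(np.isfinite(out))

    def test_single_chunk_axis_handling(self, net, inputs):
        s, d = inputs
        out = net.predict(s[0], d[0])
        assert out.shape == (60,)

    def test_eval_mode_deterministic(self, net, inputs):
        s, d = inputs
        np.testing.assert_array_equal(net.predict(s, d), net.predict(s, d))

    def test_train_mode_dropout_stochastic(self, net, inputs):
        s, d = inputs
        a = net.forward(s, d, training=True, rng=np.random.default_rng(0)).data
        b = net.forward(s, d, training=True, rng=np.random.default_rng(1)).data
        assert not np.array_equal(a, b)

    def test_zero_dynamic_input_gives_constant_waveform(self, net, inputs):
        # all temporal information enters via the dynamic branch; a freshly
        # initialized model has zero biases, so the waveform is exactly flat
        s, d = inputs
        out = net.predict(s, np.zeros_like(d))
        assert np.ptp(out, axis=1).max() < 1e-6

    def test_zeroed_parameters_give_zero_waveform(self, net, inputs):
        s, d = inputs
        for p in net.params.values():
            p.data[...] = 0.0
        assert np.all(net.predict(s, d) == 0.0)

    def test_rejects_nonfinite_input(self, net, inputs):
        s, d = inputs
        d = d.copy()
        d[0, 0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            net.predict(s, d)

    def test_rejects_wrong_spatial_size(self, net, rng):
        s = rng.standard_normal((1, 60, 20, 20, 3)).astype(np.float32)
        with pytest.raises(ValueError):
            net.predict(s, s)


class TestTemporalReceptiveField:
    def _perturb_delta(self, config, t_probe, t_perturb, rng):
        net = build_mdar(config, seed=3)
        shape = (1, config.chunk_len, config.image_size, config.image_size, 3)
        s = rng.standard_normal(shape).astype(np.float32)
        d = rng.standard_normal(shape).astype(np.float32)
        base = net.predict(s, d)[0, t_probe]
        d2 = d.copy()
        d2[0, t_perturb] += 1.0
        return abs(net.predict(s, d2)[0, t_probe] - base)

    def test_no_shifts_means_per_frame_network(self, rng):
        cfg = MDARConfig(
            stage_widths=(12,) * 6, chunk_len=12, image_size=16,
            shift=ShiftConfig(alpha1=0.0, alpha2=0.0),
        )
        assert self._perturb_delta(cfg, t_probe=5, t_perturb=6, rng=rng) < 1e-6
        assert self._perturb_delta(cfg, t_probe=5, t_perturb=5, rng=rng) > 1e-5

    def test_shifts_widen_receptive_field(self, rng):
        cfg = MDARConfig(stage_widths=(12,) * 6, chunk_len=12, image_size=16)
        for dt in (1, 2):
            assert self._perturb_delta(cfg, 5, 5 + dt, rng=rng) > 1e-7
            assert self._perturb_delta(cfg, 5, 5 - dt, rng=rng) > 1e-7


class TestConfigAndParams:
    def test_parameter_count_matches_shape_arithmetic(self, tiny_net_config, net):
        w = tiny_net_config.stage_widths
        ios_static = [(3, w[0]), (w[0], w[1]), (w[1], w[2]), (w[2], w[3]), (w[3], w[4])]
        ios_dyn = ios_static + [(w[4], w[5])]
        expected = sum(9 * ci * co + co for ci, co in ios_static + ios_dyn)
        expected += (w[1] ** 2 + w[1]) + (w[4] ** 2 + w[4])  # gating convs
        expected += (w[1] + w[4] + w[5]) + 1  # dense head
        assert net.count_parameters() == expected

    def test_count_invariant_to_seed(self, tiny_net_config):
        a = build_mdar(tiny_net_config, seed=0)
        b = build_mdar(tiny_net_config, seed=99)
        assert a.count_parameters() == b.count_parameters()

    def test_width_shift_compatibility_enforced(self):
        with pytest.raises(ValueError):
            MDARConfig(stage_widths=(8, 8, 8, 8, 8, 8), shift=ShiftConfig(1 / 4, 1 / 12))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            MDARConfig(stage_widths=(16, 16, 16))
        with pytest.raises(ValueError):
            MDARConfig(image_size=30)
        with pytest.raises(ValueError):
            MDARConfig(dropout_rates=(0.5, 1.0))

    def test_default_fractions_and_beta(self):
        cfg = MDARConfig()
        assert cfg.shift.alpha1 == pytest.approx(1 / 4)
        assert cfg.shift.alpha2 == pytest.approx(1 / 12)
        assert cfg.fusion.beta == pytest.approx(0.2)


class TestDSFFMInGraph:
    def test_graph_gate_matches_reference_operator(self, rng):
        """The engine's fused gate equals the standalone fusion operator."""
        from mdar import _engine as eng
        from mdar.fusion import dsffm

        c, n, t, h, w = 6, 2, 3, 4, 4
        r = rng.standard_normal((c, n, h, w)).astype(np.float32)
        d = rng.standard_normal((c, n * t, h, w)).astype(np.float32)
        wg = (rng.standard_normal((c, c)) * 0.4).astype(np.float32)
        bg = (rng.standard_normal(c) * 0.1).astype(np.float32)
        gate = eng.sample_norm(
            eng.silu(eng.conv1x1(eng.Tensor(r), eng.Tensor(wg), eng.Tensor(bg))), 1e-7
        )
        out = eng.gate_mul(eng.Tensor(d), gate, n, t, 0.2).data
        # reference operator works on (n, c, t, h, w) blocks
        r5 = r.transpose(1, 0, 2, 3)[:, :, None]
        d5 = d.reshape(c, n, t, h, w).transpose(1, 0, 2, 3, 4)
        ref = dsffm(r5, d5, wg, bg, FusionConfig(beta=0.2, epsilon=1e-7))
        out5 = out.reshape(c, n, t, h, w).transpose(1, 0, 2, 3, 4)
        np.testing.assert_allclose(out5, ref, rtol=1e-4, atol=1e-6)


class TestCheckpoint:
    def test_roundtrip(self, net, inputs, tmp_path):
        s, d = inputs
        before = net.predict(s, d)
        path = tmp_path / "ckpt.npz"
        net.save(path)
        from mdar.network import MDARNetwork

        loaded = MDARNetwork.load(path)
        assert loaded.config == net.config
        np.testing.assert_array_equal(loaded.predict(s, d), before)

    def test_config_yaml_export(self, net, tmp_path):
        import yaml

        net.export_config_yaml(tmp_path / "cfg.yaml")
        with open(tmp_path / "cfg.yaml") as fh:
            doc = yaml.safe_load(fh)
        assert doc["stage_widths"] == [12, 12, 12, 12, 12, 12]
        assert doc["shift"]["alpha1"] == pytest.approx(1 / 4)
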