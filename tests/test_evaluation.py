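"""Spectral heart-rate estimation, error metrics, improvement tables."""

import numpy as np
import pandas as pd
import pytest

from mdar.evaluation import (
    HRSeries,
    build_improvement_table,
    compare_with_published,
    estimate_hr,
    improvement_percent,
    load_benchmark_table,
    load_published_improvements,
    mae,
    mape,
)


def sinusoid(f, fps, seconds, rng=None, noise=0.0):
    t = np.arange(int(fps * seconds)) / fps
    x = np.sin(2 * np.pi * f * t)
    if noise:
        x = x + (rng or np.random.default_rng(0)).normal(0, noise, x.size)
    return x


class TestEstimateHR:
    def test_bin_aligned_sinusoid_exact(self):
        # 1.5 Hz over 10 s at 30 fps: the peak sits exactly on 90 bpm
        assert estimate_hr(sinusoid(1.5, 30, 10), 30) == pytest.approx(90.0, abs=0.5)

    def test_band_mask_rejects_stronger_out_of_band_peak(self):
        x = 3.0 * sinusoid(0.5, 30, 20) + 0.5 * sinusoid(1.0, 30, 20)
        assert estimate_hr(x, 30) == pytest.approx(60.0, abs=0.5)

    def test_amplitude_invariance(self):
        x = sinusoid(1.2, 30, 8)
        assert estimate_hr(x, 30) == estimate_hr(100.0 * x, 30)

    def test_noise_robustness_monte_carlo(self):
        # SNR 0 dB (noise std = signal rms): 30 s window, 95% of trials
        # within one raw frequency bin (2 bpm at 30 s)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = sinusoid(1.5, 30, 30, rng=rng, noise=1.0 / np.sqrt(2))
            hits += abs(estimate_hr(x, 30) - 90.0) <= 2.0
        assert hits >= 95

    def test_constant_waveform_rejected(self):
        with pytest.raises(ValueError):
            estimate_hr(np.ones(300), 30)

    def test_short_waveform_rejected(self):
        with pytest.raises(ValueError):
            estimate_hr(sinusoid(1.5, 30, 2), 30)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            estimate_hr(sinusoid(1.5, 30, 10), 30, band_hz=(20.0, 40.0))


class TestMetrics:
    def test_mae_zero_for_perfect_prediction(self):
        s = HRSeries(np.array([70.0, 80.0]), np.array([70.0, 80.0]))
        assert mae(s) == 0.0 and mape(s) == 0.0

    def test_mae_single_pair(self):
        s = HRSeries(np.array([92.28]), np.array([93.25]))
        assert mae(s) == pytest.approx(0.97, abs=1e-9)
        assert mape(s) == pytest.approx(1.0511, abs=1e-4)

    def test_mae_hand_sum(self):
        s = HRSeries(np.array([70.0, 80.0]), np.array([72.0, 80.0]))
        assert mae(s) == pytest.approx(1.0)

    def test_mape_simple(self):
        s = HRSeries(np.array([100.0]), np.array([90.0]))
        assert mape(s) == pytest.approx(10.0)

    def test_mape_requires_positive_reference(self):
        with pytest.raises(ValueError):
            mape(HRSeries(np.array([0.0]), np.array([1.0])))

    def test_translation_bound(self, rng):
        y = rng.uniform(60, 120, 30)
        yhat = y + rng.normal(0, 3, 30)
        base = mae(HRSeries(y, yhat))
        shifted = mae(HRSeries(y, yhat + 0.7))
        assert abs(shifted - base) <= 0.7 + 1e-12


class TestImprovement:
    def test_deepphys_cell(self):
        assert improvement_percent(3.8, 0.83) == pytest.approx(78.16, abs=0.1)

    def test_tscan_cell(self):
        assert improvement_percent(14.34, 12.86) == pytest.approx(10.3, abs=0.05)

    def test_equal_metrics_zero(self):
        assert improvement_percent(5.0, 5.0) == 0.0

    def test_closed_form_on_random_pairs(self, rng):
        for _ in range(50):
            other = rng.uniform(0.5, 20)
            ours = rng.uniform(0.5, 20)
            assert improvement_percent(other, ours) == pytest.approx(
                100 * (other - ours) / other
            )
            # not antisymmetric under swapping roles
        assert improvement_percent(2.0, 1.0) != -improvement_percent(1.0, 2.0)

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            improvement_percent(0.0, 1.0)


class TestImprovementTable:
    def test_two_method_toy_table(self):
        table = pd.DataFrame(
            {
                "method": ["A", "A", "MDAR", "MDAR"],
                "train_set": ["P", "U", "P", "U"],
                "test_set": ["U", "P", "U", "P"],
                "mae": [2.0, 4.0, 1.0, 1.0],
                "mape": [2.0, 2.0, 1.0, 1.5],
            }
        )
        out = build_improvement_table(table)
        np.testing.assert_allclose(out.cells["mae_improvement_pct"], [50.0, 75.0])
        np.testing.assert_allclose(out.cells["mape_improvement_pct"], [50.0, 25.0])
        assert out.means.loc[0, "mae_improvement_mean_pct"] == pytest.approx(62.5)

    def test_all_methods_equal_gives_zeros(self):
        rows = []
        for m in ("A", "B", "MDAR"):
            rows.append({"method": m, "train_set": "P", "test_set": "U", "mae": 2.0, "mape": 3.0})
        out = build_improvement_table(pd.DataFrame(rows))
        assert np.all(out.cells[["mae_improvement_pct", "mape_improvement_pct"]] == 0)

    def test_missing_reference_rejected(self):
        df = pd.DataFrame(
            {"method": ["A"], "train_set": ["P"], "test_set": ["U"], "mae": [1.0], "mape": [1.0]}
        )
        with pytest.raises(ValueError):
            build_improvement_table(df)

    def test_packaged_benchmark_shape(self):
        table = load_benchmark_table()
        assert len(table) == 24  # six methods x four train/test combinations
        assert set(table["method"]).issuperset({"MDAR", "TS-CAN", "DeepPhys"})

    def test_known_discrepant_cell_is_flagged(self):
        diff = compare_with_published()
        flagged = diff[diff["discrepant"]]
        assert len(flagged) == 1
        row = flagged.iloc[0]
        assert row["method"] == "PhysNet"
        assert (row["train_set"], row["test_set"]) == ("UBFC-rPPG", "MMPD")
        assert row["mae_improvement_pct_recomputed"] == pytest.approx(-12.06, abs=0.05)

    def test_published_means_table_consistency(self):
        cells, means = load_published_improvements()
        assert len(cells) == 20 and len(means) == 5
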