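"""Tests for position-binned rates and logistic-GLM ramp classification."""

import numpy as np
import pandas as pd
import pytest

from calspike.core import SpikeTrain
from calspike.ramps import (
    moving_average_rate,
    position_binned_rate,
    ramp_glm_classify,
    ramp_linear_change,
)
from calspike.synthetic import SimulationConfig, generate_vr_session


def constant_speed_track(n_trials=1, speed=32.0, rate_hz=30.0):
    """Track sweeping −30 → 290 cm at constant speed, per trial."""
    dt = 1.0 / rate_hz
    n = int(np.ceil(320.0 / speed / dt))
    rows = []
    t0 = 0.0
    for k in range(n_trials):
        t = t0 + np.arange(n) * dt
        rows.append(pd.DataFrame({
            "time_s": t,
            "position_cm": np.minimum(-30.0 + speed * (t - t0), 290.0),
            "trial_id": k,
        }))
        t0 = t[-1] + dt
    return pd.concat(rows, ignore_index=True)


class TestBinnedRate:
    def test_toy_arithmetic(self):
        # 0.5 s of occupancy in one bin with 2 spikes -> 4 Hz
        dt = 0.05
        track = pd.DataFrame({
            "time_s": np.arange(10) * dt,
            "position_cm": np.full(10, 5.0),  # bin [0, 10)
            "trial_id": 0,
        })
        spikes = np.array([0.1, 0.3])
        centers, rates, occ = position_binned_rate(spikes, track)
        b = np.digitize(5.0, np.arange(-30, 291, 10)) - 1
        assert occ[b] == pytest.approx(0.5)
        assert rates[b] == pytest.approx(4.0)

    def test_unvisited_bins_are_missing(self):
        track = constant_speed_track()
        track = track[track["position_cm"] < 100.0]
        _, rates, _ = position_binned_rate(np.array([]), track)
        assert np.isnan(rates[-1])  # last bin never visited
        assert not np.isnan(rates[0])

    def test_spike_conservation(self, rng):
        track = constant_speed_track(n_trials=3)
        duration = track["time_s"].max()
        spikes = np.sort(rng.uniform(0, duration, 200))
        centers, rates, occ = position_binned_rate(spikes, track)
        ok = occ > 0
        total = np.sum(rates[ok] * occ[ok])
        assert total == pytest.approx(len(spikes), abs=1)

    def test_stationary_rate_recovered(self):
        rng = np.random.default_rng(0)
        track = constant_speed_track(n_trials=40)
        duration = track["time_s"].max()
        spikes = np.sort(rng.uniform(0, duration, int(5 * duration)))
        _, rates, occ = position_binned_rate(spikes, track)
        ok = occ > 0
        se = np.sqrt(5.0 / occ[ok])
        assert np.all(np.abs(rates[ok] - 5.0) < 4 * se)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            position_binned_rate(np.array([1.0]), pd.DataFrame())


class TestMovingAverage:
    def test_degenerate_stride_equals_binned(self, rng):
        track = constant_speed_track(n_trials=2)
        spikes = np.sort(rng.uniform(0, track["time_s"].max(), 100))
        centers_b, rates_b, occ = position_binned_rate(spikes, track)
        centers_m, rates_m = moving_average_rate(spikes, track, 10.0, 10.0)
        np.testing.assert_allclose(centers_m, centers_b)
        np.testing.assert_allclose(rates_m, rates_b, rtol=1e-9)

    def test_flat_profile_for_constant_rate(self):
        rng = np.random.default_rng(1)
        track = constant_speed_track(n_trials=30)
        duration = track["time_s"].max()
        spikes = np.sort(rng.uniform(0, duration, int(6 * duration)))
        _, rates = moving_average_rate(spikes, track)
        ok = np.isfinite(rates)
        assert np.nanstd(rates[ok]) < 2.0  # sampling noise only, no trend
        assert abs(np.nanmean(rates[ok]) - 6.0) < 1.0

    def test_unoccupied_window_missing(self):
        track = constant_speed_track()
        track = track[track["position_cm"] > 50.0]
        _, rates = moving_average_rate(np.array([]), track)
        assert np.isnan(rates[0])


class TestLinearChange:
    def test_exact_linear_profile(self):
        centers = np.arange(-25.0, 290.0, 10.0)
        rates = 3.0 + 0.01 * centers
        slope, change = ramp_linear_change(centers, rates)
        assert slope == pytest.approx(0.01)
        assert change == pytest.approx(2.9)

    def test_flat_profile(self):
        centers = np.arange(-25.0, 290.0, 10.0)
        _, change = ramp_linear_change(centers, np.full(len(centers), 4.0))
        assert change == pytest.approx(0.0, abs=1e-12)

    def test_offset_equivariance(self, rng):
        centers = np.arange(-25.0, 290.0, 10.0)
        rates = rng.uniform(2, 8, len(centers))
        s1, _ = ramp_linear_change(centers, rates)
        s2, _ = ramp_linear_change(centers, rates + 5.0)
        assert s1 == pytest.approx(s2)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            ramp_linear_change([0.0, 10.0], [1.0, 2.0])


def _vr_indicators(rec):
    """Per-timestep spike indicators aligned to the track clock."""
    cfg = rec.config
    n = len(rec.track)
    idx = np.minimum(
        (rec.spikes.times_s * cfg.frame_rate_hz).astype(int), n - 1
    )
    ind = np.zeros(n)
    ind[idx] = 1.0
    return ind


class TestGLM:
    def test_no_spikes_classified_none(self):
        fit = ramp_glm_classify(np.zeros(500), np.linspace(-30, 290, 500),
                                np.repeat([0, 1], 250))
        assert fit.classification == "none"

    def test_strong_up_ramp_detected(self):
        cfg = SimulationConfig(seed=21, frame_rate_hz=30.0, tonic_rate_hz=2.0,
                               burst_rate_hz=0.0)
        rec = generate_vr_session(cfg, ramp_slope_hz_per_s=0.8, n_trials=40)
        fit = ramp_glm_classify(
            _vr_indicators(rec),
            rec.track["position_cm"].to_numpy(),
            rec.track["trial_id"].to_numpy(),
        )
        assert fit.classification == "up"

    def test_strong_down_ramp_detected(self):
        cfg = SimulationConfig(seed=22, frame_rate_hz=30.0, tonic_rate_hz=10.0,
                               burst_rate_hz=0.0)
        rec = generate_vr_session(cfg, ramp_slope_hz_per_s=-0.8, n_trials=40)
        fit = ramp_glm_classify(
            _vr_indicators(rec),
            rec.track["position_cm"].to_numpy(),
            rec.track["trial_id"].to_numpy(),
        )
        assert fit.classification == "down"

    def test_null_type_i_control(self):
        n_false = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, frame_rate_hz=30.0,
                                   tonic_rate_hz=6.0, burst_rate_hz=0.0)
            rec = generate_vr_session(cfg, ramp_slope_hz_per_s=0.0, n_trials=20)
            fit = ramp_glm_classify(
                _vr_indicators(rec),
                rec.track["position_cm"].to_numpy(),
                rec.track["trial_id"].to_numpy(),
            )
            n_false += fit.classification != "none"
        assert n_false <= 2

    def test_glm_sign_agrees_with_linear_fit(self):
        cfg = SimulationConfig(seed=30, frame_rate_hz=30.0, tonic_rate_hz=3.0,
                               burst_rate_hz=0.0)
        rec = generate_vr_session(cfg, ramp_slope_hz_per_s=0.5, n_trials=30)
        duration = rec.track["time_s"].max() + 1 / 30.0
        spikes = SpikeTrain(rec.spikes.times_s, duration)
        centers, rates, _ = position_binned_rate(spikes, rec.track)
        slope, _ = ramp_linear_change(centers, rates)
        fit = ramp_glm_classify(
            _vr_indicators(rec),
            rec.track["position_cm"].to_numpy(),
            rec.track["trial_id"].to_numpy(),
        )
        assert np.sign(slope) == np.sign(fit.position_coefficient) == 1.0

    def test_non_binary_indicator_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            ramp_glm_classify(np.array([0.0, 2.0]), np.array([0.0, 1.0]),
                              np.array([0, 0]))
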