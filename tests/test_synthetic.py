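"""Tests for the ground-truth simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calspike.evaluation import burst_fraction
from calspike.synthetic import (
    ResponseParams,
    SimulationConfig,
    forward_calcium,
    generate_pavlovian_schedule,
    generate_pavlovian_session,
    generate_spike_train,
    generate_vr_session,
)


class TestSpikeTrain:
    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_sorted_and_bounded_for_all_seeds(self, seed):
        cfg = SimulationConfig(seed=seed, duration_s=20.0)
        train = generate_spike_train(cfg)
        t = train.times_s
        assert np.all(np.diff(t) >= 0)
        assert t.size == 0 or (t[0] >= 0 and t[-1] <= 20.0)

    def test_zero_duration_gives_empty_train(self):
        assert len(generate_spike_train(SimulationConfig(duration_s=0.0))) == 0

    def test_burstless_train_is_pacemaker_like(self):
        cfg = SimulationConfig(
            seed=11, duration_s=100.0, tonic_rate_hz=4.0, burst_rate_hz=0.0,
            isi_shape=4.0,
        )
        summary = burst_fraction(generate_spike_train(cfg))
        assert summary.burst_fraction < 0.10
        assert summary.is_pacemaker

    def test_mean_count_matches_renewal_expectation(self):
        # law of large numbers: mean count over seeds within 3 SE of rate*T
        counts = [
            len(generate_spike_train(SimulationConfig(
                seed=s, duration_s=1000.0, tonic_rate_hz=6.0, burst_rate_hz=0.0
            )))
            for s in range(20)
        ]
        counts = np.asarray(counts, float)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 6000.0) < 3 * max(se, 1.0)

    def test_rate_profile_modulates_local_rate(self):
        cfg = SimulationConfig(seed=3, duration_s=200.0, burst_rate_hz=0.0,
                               tonic_rate_hz=5.0)
        train = generate_spike_train(
            cfg, rate_profile=lambda t: 10.0 if t < 100.0 else 1.0
        )
        first = np.sum(train.times_s < 100.0)
        second = len(train) - first
        assert first > 3 * second

    def test_nonfinite_profile_rejected_with_time(self):
        cfg = SimulationConfig(seed=0, duration_s=1.0)
        with pytest.raises(ValueError, match="non-finite at t"):
            generate_spike_train(cfg, rate_profile=lambda t: np.nan if t > 0.5 else 5.0)


class TestForwardModel:
    def test_no_spikes_no_noise_is_flat_baseline(self):
        cfg = SimulationConfig(
            duration_s=10.0, noise_sd=0.0, drift_amplitude=0.0,
            linear_trend_per_s=0.0, baseline_level=1.5,
        )
        from calspike.core import SpikeTrain

        out = forward_calcium(SpikeTrain(np.empty(0), 10.0), cfg)
        np.testing.assert_allclose(out.values, 1.5, atol=1e-12)

    def test_single_spike_impulse_response(self):
        cfg = SimulationConfig(
            duration_s=10.0, noise_sd=0.0, drift_amplitude=0.0,
            linear_trend_per_s=0.0, baseline_level=0.0, amplitude_cv=0.0,
            spike_amplitude=2.0, gamma_per_step=0.97, frame_rate_hz=10.0,
        )
        from calspike.core import SpikeTrain

        out = forward_calcium(SpikeTrain(np.array([5.0]), 10.0), cfg)
        k = 50  # frame of the spike
        np.testing.assert_allclose(
            out.values[k:], 2.0 * 0.97 ** np.arange(50), rtol=1e-12
        )
        np.testing.assert_allclose(out.values[:k], 0.0, atol=1e-12)

    def test_deterministic_when_noiseless(self):
        cfg = SimulationConfig(seed=5, duration_s=15.0, noise_sd=0.0, amplitude_cv=0.0)
        spikes = generate_spike_train(cfg)
        a = forward_calcium(spikes, cfg).values
        b = forward_calcium(spikes, cfg).values
        np.testing.assert_array_equal(a, b)

    def test_length_contract(self):
        cfg = SimulationConfig(duration_s=12.0, frame_rate_hz=33.33)
        spikes = generate_spike_train(cfg)
        assert len(forward_calcium(spikes, cfg)) == round(12.0 * 33.33)


class TestPavlovian:
    def test_trial_type_counts_and_ordering(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            events, _ = generate_pavlovian_schedule(rng)
            by_trial = events.groupby("trial_id")["event_type"].apply(set)
            n_std = sum(1 for s in by_trial if s == {"cue_onset", "reward"})
            n_ur = sum(1 for s in by_trial if s == {"unexpected_reward"})
            n_om = sum(1 for s in by_trial if s == {"cue_onset", "omission_onset"})
            assert (n_std, n_ur, n_om) == (50, 7, 7)
            # first five trials standard
            for k in range(5):
                assert by_trial[k] == {"cue_onset", "reward"}
            # first two non-standard trials are unexpected rewards
            nonstd = [tid for tid in sorted(by_trial.index)
                      if by_trial[tid] != {"cue_onset", "reward"}]
            assert by_trial[nonstd[0]] == {"unexpected_reward"}
            assert by_trial[nonstd[1]] == {"unexpected_reward"}

    def test_iti_mean_matches_exponential(self):
        rng = np.random.default_rng(1)
        itis = np.concatenate(
            [generate_pavlovian_schedule(rng)[1] for _ in range(200)]
        )
        se = itis.std(ddof=1) / np.sqrt(len(itis))
        assert abs(itis.mean() - 40.0) < 3 * se

    def test_cue_precedes_reward_by_two_seconds(self):
        rng = np.random.default_rng(2)
        events, _ = generate_pavlovian_schedule(rng)
        std = events.pivot_table(index="trial_id", columns="event_type",
                                 values="time_s")
        mask = std["reward"].notna() & std["cue_onset"].notna()
        np.testing.assert_allclose(
            std.loc[mask, "reward"] - std.loc[mask, "cue_onset"], 2.0
        )

    def test_session_recording_is_consistent(self):
        cfg = SimulationConfig(seed=9, frame_rate_hz=30.0)
        rec = generate_pavlovian_session(cfg, ResponseParams())
        assert len(rec.fluorescence) == round(rec.config.duration_s * 30.0)
        assert rec.spikes.times_s[-1] <= rec.config.duration_s
        assert rec.events is not None and len(rec.events) > 64

    def test_negative_rate_params_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ResponseParams(pause_depth=1.5)
        with pytest.raises(ValueError, match="negative"):
            ResponseParams(cue_peak_hz=-1.0)


class TestVR:
    def test_track_bounds_and_trials(self):
        cfg = SimulationConfig(seed=4, frame_rate_hz=30.0)
        rec = generate_vr_session(cfg, ramp_slope_hz_per_s=0.2, n_trials=5)
        track = rec.track
        assert track["position_cm"].between(-30, 290).all()
        assert set(track["trial_id"]) == set(range(5))
        for _, grp in track.groupby("trial_id"):
            assert np.all(np.diff(grp["time_s"]) > 0)

    def test_positive_slope_concentrates_late_spikes(self):
        cfg = SimulationConfig(seed=8, frame_rate_hz=30.0, tonic_rate_hz=2.0,
                               burst_rate_hz=0.0)
        rec = generate_vr_session(cfg, ramp_slope_hz_per_s=1.0, n_trials=20)
        pos = np.interp(rec.spikes.times_s, rec.track["time_s"], rec.track["position_cm"])
        assert np.median(pos) > 130.0  # well past the maze midpoint
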