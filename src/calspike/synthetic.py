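"""Ground-truth simulator for tonically active dopamine neurons.

Generates paired spike trains and fluorescence so that the full inference
pipeline (preprocess → L0 deconvolution → validation / event / ramp
analyses) can be exercised without any recorded data.

The firing model is a gamma-renewal process (shape 1 recovers Poisson) at a
tonic rate of a few Hz, optionally modulated by a time-varying rate profile
via time rescaling, with bursts (≥3 spikes, inter-spike intervals ≤100 ms)
overlaid at exponentially distributed onset times.  Fluorescence follows the
AR(1) calcium model: calcium decays by a per-timestep factor γ between
spikes and jumps instantaneously at spikes, observed with additive Gaussian
noise on top of a baseline, a slow sinusoidal drift and a linear trend.

Three session types are provided: plain in-vitro-like recordings, Pavlovian
conditioning sessions (50 cued-reward + 7 unexpected-reward + 7 omission
trials with exponential inter-trial intervals, mean 40 s), and
virtual-reality maze sessions (−30 to 290 cm) with position/time-ramping
firing rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import FluorescenceTrace, SpikeTrain

__all__ = [
    "SimulationConfig",
    "ResponseParams",
    "GroundTruthRecording",
    "generate_spike_train",
    "forward_calcium",
    "generate_pavlovian_schedule",
    "generate_pavlovian_session",
    "generate_vr_session",
]

#: resolution of the rate-profile grid used for time rescaling
_PROFILE_DT_S = 0.001


@dataclass
class SimulationConfig:
    """Parameters of a simulated recording.

    Defaults describe a burst-firing dopamine neuron imaged with a
    fast calcium indicator at 33.33 Hz: 6 Hz tonic rate, a burst every
    five seconds on average, per-frame calcium decay 0.95 (≈0.975 per
    step once resampled to 66.67 Hz), unit transient amplitude and
    moderate observation noise over a slowly drifting baseline.
    """

    seed: int = 0
    duration_s: float = 120.0
    frame_rate_hz: float = 33.33
    tonic_rate_hz: float = 6.0
    isi_shape: float = 2.0
    burst_rate_hz: float = 0.2
    burst_size_range: tuple[int, int] = (3, 6)
    intra_burst_isi_s: tuple[float, float] = (0.02, 0.08)
    gamma_per_step: float = 0.95
    spike_amplitude: float = 1.0
    amplitude_cv: float = 0.2
    noise_sd: float = 0.05
    baseline_level: float = 1.0
    drift_amplitude: float = 0.1
    drift_period_s: float = 60.0
    linear_trend_per_s: float = 0.001

    def __post_init__(self) -> None:
        if not 0 < self.gamma_per_step < 1:
            raise ValueError("gamma_per_step must be in (0, 1)")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.burst_size_range[0] < 3:
            raise ValueError("bursts must contain at least 3 spikes")
        if not 0 < self.intra_burst_isi_s[1] <= 0.1:
            raise ValueError("intra-burst inter-spike intervals must be within (0, 0.1] s")
        if self.duration_s < 0 or self.tonic_rate_hz < 0 or self.burst_rate_hz < 0:
            raise ValueError("durations and rates must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        """Named random generator: all randomness flows from the one seed."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class ResponseParams:
    """Event-locked firing-rate modulation for Pavlovian sessions.

    Cue and reward responses are Gaussian rate bumps (peak height in Hz
    above the tonic rate); omission is a fractional pause of the tonic
    rate over a fixed window after the expected-reward time.
    """

    cue_peak_hz: float = 10.0
    cue_latency_s: float = 0.3
    cue_sd_s: float = 0.15
    reward_peak_hz: float = 16.0
    reward_latency_s: float = 0.25
    reward_sd_s: float = 0.12
    pause_depth: float = 0.9
    pause_duration_s: float = 1.3

    def __post_init__(self) -> None:
        if self.cue_peak_hz < 0 or self.reward_peak_hz < 0:
            raise ValueError("response peaks must be non-negative (rates cannot go negative)")
        if not 0 <= self.pause_depth <= 1:
            raise ValueError("pause_depth must be in [0, 1] (rates cannot go negative)")


@dataclass
class GroundTruthRecording:
    """A simulated session: fluorescence, true spikes and any metadata."""

    fluorescence: FluorescenceTrace
    spikes: SpikeTrain
    config: SimulationConfig
    events: pd.DataFrame | None = None
    track: pd.DataFrame | None = None


def _renewal_arrivals(rng, total_mass: float, shape: float) -> np.ndarray:
    """Arrival times of a unit-rate gamma-renewal process on [0, total_mass]."""
    if total_mass <= 0:
        return np.empty(0)
    # draw in blocks until the cumulative sum covers the interval
    n_guess = max(16, int(total_mass * 1.5) + 8 * int(np.sqrt(total_mass) + 1))
    isis = rng.gamma(shape, 1.0 / shape, size=n_guess)
    while isis.sum() < total_mass:
        isis = np.concatenate([isis, rng.gamma(shape, 1.0 / shape, size=n_guess)])
    arrivals = np.cumsum(isis)
    return arrivals[arrivals <= total_mass]


def generate_spike_train(config: SimulationConfig, rate_profile=None) -> SpikeTrain:
    """Simulate tonic + burst spiking.

    Tonic spikes come from a gamma-renewal process with mean rate
    ``config.tonic_rate_hz`` (shape ``config.isi_shape``); if
    ``rate_profile`` (a callable ``t → Hz``) is given the renewal process
    is warped through its cumulative intensity (time rescaling), so the
    local rate follows the profile.  Bursts are overlaid at exponentially
    distributed onsets with ``burst_rate_hz``; each burst is a run of
    ``burst_size_range`` spikes with intra-burst inter-spike intervals
    drawn uniformly from ``intra_burst_isi_s``.
    """
    T = float(config.duration_s)
    if T <= 0:
        return SpikeTrain(np.empty(0), max(T, 0.0))
    rng = config.rng(1)

    if rate_profile is None:
        mass = config.tonic_rate_hz * T
        warped = _renewal_arrivals(rng, mass, config.isi_shape)
        tonic = warped / config.tonic_rate_hz if config.tonic_rate_hz > 0 else np.empty(0)
    else:
        grid = np.arange(0.0, T + _PROFILE_DT_S, _PROFILE_DT_S)
        rates = np.asarray([rate_profile(t) for t in grid], dtype=float)
        if not np.all(np.isfinite(rates)):
            t_bad = grid[int(np.flatnonzero(~np.isfinite(rates))[0])]
            raise ValueError(f"rate_profile is non-finite at t = {t_bad:.3f} s")
        if np.any(rates < 0):
            t_bad = grid[int(np.flatnonzero(rates < 0)[0])]
            raise ValueError(f"rate_profile is negative at t = {t_bad:.3f} s")
        cum = np.concatenate([[0.0], np.cumsum((rates[1:] + rates[:-1]) / 2 * np.diff(grid))])
        warped = _renewal_arrivals(rng, cum[-1], config.isi_shape)
        tonic = np.interp(warped, cum, grid)

    spikes = [tonic]
    if config.burst_rate_hz > 0:
        n_bursts = rng.poisson(config.burst_rate_hz * T)
        onsets = np.sort(rng.uniform(0.0, T, size=n_bursts))
        lo, hi = config.burst_size_range
        for onset in onsets:
            size = int(rng.integers(lo, hi + 1))
            isis = rng.uniform(*config.intra_burst_isi_s, size=size - 1)
            spikes.append(onset + np.concatenate([[0.0], np.cumsum(isis)]))
    times = np.sort(np.concatenate(spikes))
    return SpikeTrain(times[(times >= 0) & (times <= T)], T)


def forward_calcium(spikes: SpikeTrain, config: SimulationConfig) -> FluorescenceTrace:
    """AR(1) forward model: spikes → noisy fluorescence.

    Per frame ``t``, calcium is ``c_t = γ·c_{t−1} + z_t`` where ``z_t``
    sums the amplitudes of all spikes landing in frame ``t`` (the
    inference model allows one jump per timestep, so same-frame spikes
    merge).  The observation adds baseline, sinusoidal drift, linear
    trend and white Gaussian noise.
    """
    n = int(round(config.duration_s * config.frame_rate_hz))
    rng = config.rng(2)
    impulses = np.zeros(n)
    if len(spikes) and n > 0:
        idx = spikes.frame_indices(config.frame_rate_hz)
        if config.amplitude_cv > 0:
            k = 1.0 / config.amplitude_cv**2
            amps = rng.gamma(k, config.spike_amplitude / k, size=len(spikes))
        else:
            amps = np.full(len(spikes), config.spike_amplitude)
        np.add.at(impulses, idx, amps)
    calcium = lfilter([1.0], [1.0, -config.gamma_per_step], impulses)
    t = np.arange(n) / config.frame_rate_hz
    baseline = (
        config.baseline_level
        + config.drift_amplitude * np.sin(2 * np.pi * t / config.drift_period_s)
        + config.linear_trend_per_s * t
    )
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
    return FluorescenceTrace(calcium + baseline + noise, config.frame_rate_hz)


# ---------------------------------------------------------------------------
# Pavlovian sessions


def generate_pavlovian_schedule(rng: np.random.Generator, iti_mean_s: float = 40.0):
    """Trial types and event times for one conditioning test session.

    64 trials: 50 standard (cue then reward 2 s later), 7 unexpected
    reward, 7 omission.  The first five trials are standard and the first
    two non-standard trials are unexpected-reward; inter-trial intervals
    are exponential with the given mean.  Returns ``(events, itis)``.
    """
    kinds = ["standard"] * 5
    positions = np.sort(rng.choice(59, size=14, replace=False))
    rest = np.array(["standard"] * 59, dtype=object)
    rest[positions[:2]] = "unexpected"
    tail = np.array(["unexpected"] * 5 + ["omission"] * 7, dtype=object)
    rng.shuffle(tail)
    rest[positions[2:]] = tail
    kinds += list(rest)

    itis = rng.exponential(iti_mean_s, size=len(kinds))
    rows = []
    t = itis[0]
    for k, kind in enumerate(kinds):
        if kind == "standard":
            rows.append((k, "cue_onset", t))
            rows.append((k, "reward", t + 2.0))
            t_end = t + 2.0
        elif kind == "unexpected":
            rows.append((k, "unexpected_reward", t))
            t_end = t
        else:
            rows.append((k, "cue_onset", t))
            rows.append((k, "omission_onset", t + 2.0))
            t_end = t + 2.0
        if k + 1 < len(kinds):
            t = t_end + itis[k + 1]
    events = pd.DataFrame(rows, columns=["trial_id", "event_type", "time_s"])
    return events, itis


def generate_pavlovian_session(
    config: SimulationConfig, response_params: ResponseParams | None = None
) -> GroundTruthRecording:
    """Simulate a full Pavlovian test session (spikes + fluorescence + events).

    The firing-rate profile is the tonic rate plus cue- and reward-locked
    Gaussian bumps, with a fractional pause after omission onset; spikes
    are drawn through :func:`generate_spike_train` and fluorescence
    through :func:`forward_calcium`.  The session duration is set by the
    event schedule (config.duration_s is overridden).
    """
    rp = response_params or ResponseParams()
    rng = config.rng(3)
    events, _ = generate_pavlovian_schedule(rng)
    duration = float(events["time_s"].max() + 10.0)

    grid = np.arange(0.0, duration + _PROFILE_DT_S, _PROFILE_DT_S)
    rate = np.full(grid.shape, float(config.tonic_rate_hz))

    def _bump(center, peak, sd):
        lo = np.searchsorted(grid, center - 5 * sd)
        hi = np.searchsorted(grid, center + 5 * sd)
        rate[lo:hi] += peak * np.exp(-((grid[lo:hi] - center) ** 2) / (2 * sd**2))

    for _, row in events.iterrows():
        t0 = row["time_s"]
        if row["event_type"] == "cue_onset":
            _bump(t0 + rp.cue_latency_s, rp.cue_peak_hz, rp.cue_sd_s)
        elif row["event_type"] in ("reward", "unexpected_reward"):
            _bump(t0 + rp.reward_latency_s, rp.reward_peak_hz, rp.reward_sd_s)
        else:  # omission pause
            lo = np.searchsorted(grid, t0)
            hi = np.searchsorted(grid, t0 + rp.pause_duration_s)
            rate[lo:hi] -= rp.pause_depth * config.tonic_rate_hz

    rate = np.maximum(rate, 0.0)
    from dataclasses import replace

    cfg = replace(config, duration_s=duration)
    spikes = _spikes_from_profile(cfg, grid, rate)
    fluor = forward_calcium(spikes, cfg)
    return GroundTruthRecording(fluor, spikes, cfg, events=events)


def _spikes_from_profile(config, grid, rates) -> SpikeTrain:
    """Time-rescaled renewal spikes from a precomputed rate grid, plus bursts."""
    rng = config.rng(1)
    cum = np.concatenate([[0.0], np.cumsum((rates[1:] + rates[:-1]) / 2 * np.diff(grid))])
    warped = _renewal_arrivals(rng, cum[-1], config.isi_shape)
    tonic = np.interp(warped, cum, grid)
    spikes = [tonic]
    T = float(config.duration_s)
    if config.burst_rate_hz > 0:
        n_bursts = rng.poisson(config.burst_rate_hz * T)
        onsets = np.sort(rng.uniform(0.0, T, size=n_bursts))
        lo, hi = config.burst_size_range
        for onset in onsets:
            size = int(rng.integers(lo, hi + 1))
            isis = rng.uniform(*config.intra_burst_isi_s, size=size - 1)
            spikes.append(onset + np.concatenate([[0.0], np.cumsum(isis)]))
    times = np.sort(np.concatenate(spikes))
    return SpikeTrain(times[(times >= 0) & (times <= T)], T)


# ---------------------------------------------------------------------------
# Virtual-reality sessions


def generate_vr_session(
    config: SimulationConfig,
    ramp_slope_hz_per_s: float,
    n_trials: int,
) -> GroundTruthRecording:
    """Simulate maze traversals with a linear within-trial firing ramp.

    Each trial runs from −30 to 290 cm at a variable speed (base speed
    drawn per trial, with slow sinusoidal modulation).  The firing rate
    within a trial is ``max(0, tonic_rate + slope·(t − trial_start))``,
    so positive slopes produce up-ramps toward the end of the maze.
    Trials are concatenated back-to-back into one recording.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = config.rng(4)
    dt = 1.0 / config.frame_rate_hz

    pos_parts, trial_parts, rate_parts = [], [], []
    for k in range(n_trials):
        v0 = rng.uniform(20.0, 30.0)
        phase = rng.uniform(0, 2 * np.pi)
        pos = [-30.0]
        while pos[-1] < 290.0:
            t_loc = (len(pos) - 1) * dt
            v = v0 * (1.0 + 0.25 * np.sin(2 * np.pi * t_loc / 7.0 + phase))
            pos.append(pos[-1] + v * dt)
        pos = np.asarray(pos[:-1])  # drop the sample that crossed the end
        pos = np.clip(pos, -30.0, 290.0)
        t_loc = np.arange(len(pos)) * dt
        pos_parts.append(pos)
        trial_parts.append(np.full(len(pos), k, dtype=int))
        rate_parts.append(np.maximum(config.tonic_rate_hz + ramp_slope_hz_per_s * t_loc, 0.0))

    positions = np.concatenate(pos_parts)
    trial_ids = np.concatenate(trial_parts)
    frame_rates = np.concatenate(rate_parts)
    n = len(positions)
    duration = n * dt
    times = np.arange(n) * dt

    from dataclasses import replace

    cfg = replace(config, duration_s=duration)
    spikes = _spikes_from_profile(cfg, times, frame_rates)
    fluor = forward_calcium(spikes, cfg)
    track = pd.DataFrame(
        {"time_s": times, "position_cm": positions, "trial_id": trial_ids}
    )
    return GroundTruthRecording(fluor, spikes, cfg, track=track)
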