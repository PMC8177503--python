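"""Shared containers for fluorescence traces and spike trains.

A :class:`FluorescenceTrace` is a uniformly sampled per-ROI intensity (raw
fluorescence) or normalized ΔF/F series together with its sampling rate.
A :class:`SpikeTrain` is a sorted list of spike times in seconds over a known
recording duration; it is used both for ground-truth (electrophysiology or
simulated) spikes and for spikes inferred from fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FluorescenceTrace", "SpikeTrain"]


@dataclass
class FluorescenceTrace:
    """A uniformly sampled fluorescence time series.

    Parameters
    ----------
    values
        Sample values, raw fluorescence units or dimensionless ΔF/F.
    sampling_rate_hz
        Sampling rate in Hz; must be positive.
    start_time_s
        Time of the first sample in seconds.
    """

    values: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ValueError(f"non-finite fluorescence value at index {bad}")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        """Sample times in seconds (time of frame t is t / rate + start)."""
        return self.start_time_s + np.arange(len(self)) / self.sampling_rate_hz


@dataclass
class SpikeTrain:
    """Sorted spike times over a recording of known duration."""

    times_s: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1:
            raise ValueError("spike times must be 1-D")
        if self.times_s.size and np.any(np.diff(self.times_s) < 0):
            raise ValueError("spike times must be sorted")
        if self.times_s.size and (
            self.times_s[0] < 0 or self.times_s[-1] > self.duration_s
        ):
            raise ValueError("spike times must lie within [0, duration_s]")

    def __len__(self) -> int:
        return self.times_s.size

    @property
    def rate_hz(self) -> float:
        """Mean firing rate: spike count divided by recording duration."""
        if self.duration_s <= 0:
            return 0.0
        return len(self) / self.duration_s

    def frame_indices(self, sampling_rate_hz: float) -> np.ndarray:
        """Timestep index of each spike at the given sampling rate."""
        return np.minimum(
            np.floor(self.times_s * sampling_rate_hz).astype(int),
            int(round(self.duration_s * sampling_rate_hz)) - 1,
        )
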