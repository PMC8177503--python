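"""Peri-stimulus firing-rate analysis for reward, cue and omission events.

Spike times are aligned to behavioral events, histogrammed in 1 ms bins
over a ±4 s window (spike times rounded to the nearest millisecond),
converted to a trial-averaged instantaneous rate, and smoothed with a
unit-sum Gaussian kernel (200 ms support, 40 ms SD).  Windowed response
statistics are computed from raw counts, not the smoothed PSTH:

* reward response   — mean rate 0–600 ms after reward onset;
* cue response      — mean rate in a 500 ms window starting 150 ms after cue;
* omission response — mean rate 0–1300 ms after omission onset;

each baseline-subtracted using the 1 s window immediately before the
event (or before the cue for expected-reward and omission trials).  A
neuron has a significant omission pause when a paired t-test across
trials rejects at p < 0.05 *and* the mean omission response is below
baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ttest_rel

from .core import SpikeTrain

__all__ = [
    "PSTH",
    "ResponseWindows",
    "PeakResult",
    "build_psth",
    "event_response",
    "peak_and_fdhm",
    "omission_significance",
]

BIN_S = 0.001
KERNEL_WIDTH_S = 0.200
KERNEL_SD_S = 0.040


@dataclass
class ResponseWindows:
    """Analysis windows in seconds relative to the event."""

    baseline: tuple[float, float] = (-1.0, 0.0)
    reward: tuple[float, float] = (0.0, 0.6)
    cue: tuple[float, float] = (0.15, 0.65)
    omission: tuple[float, float] = (0.0, 1.3)
    #: variant cue window (first 500 ms post-cue) used in some analyses
    cue_alt: tuple[float, float] = (0.0, 0.5)


@dataclass
class PSTH:
    bin_centers_s: np.ndarray
    rate_hz: np.ndarray
    n_trials: int
    kernel: np.ndarray = field(repr=False, default=None)


def gaussian_kernel(
    bin_s: float = BIN_S, width_s: float = KERNEL_WIDTH_S, sd_s: float = KERNEL_SD_S
) -> np.ndarray:
    """Unit-sum Gaussian smoothing kernel truncated to ±width/2."""
    half = int(round(width_s / 2 / bin_s))
    x = np.arange(-half, half + 1) * bin_s
    k = np.exp(-(x**2) / (2 * sd_s**2))
    return k / k.sum()


def build_psth(
    spikes: SpikeTrain | np.ndarray,
    events,
    window_s: float = 4.0,
    smooth: bool = True,
) -> PSTH:
    """Trial-averaged smoothed firing rate aligned to events.

    Rate per 1 ms bin is (spike count across trials)/(n_trials × 1 ms),
    then convolved with the unit-sum Gaussian kernel.  Spike times are
    rounded to the nearest millisecond before binning.
    """
    t = spikes.times_s if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValueError("need at least one event to build a PSTH")
    nbins = int(round(2 * window_s / BIN_S))
    edges = np.linspace(-window_s, window_s, nbins + 1)
    counts = np.zeros(nbins)
    for ev in events:
        rel = np.round((t - ev) / BIN_S) * BIN_S
        sel = rel[(rel >= -window_s) & (rel < window_s)]
        counts += np.histogram(sel, bins=edges)[0]
    rate = counts / (len(events) * BIN_S)
    if smooth:
        kernel = gaussian_kernel()
        rate = np.convolve(rate, kernel, mode="same")
    else:
        kernel = None
    centers = (edges[:-1] + edges[1:]) / 2
    return PSTH(centers, rate, len(events), kernel)


def _window_rate(t, events, window):
    lo, hi = window
    count = 0
    for ev in events:
        count += int(np.sum((t >= ev + lo) & (t < ev + hi)))
    return count / ((hi - lo) * len(events))


def event_response(
    spikes: SpikeTrain | np.ndarray,
    events,
    window: tuple[float, float],
    baseline_window: tuple[float, float] = (-1.0, 0.0),
) -> float:
    """Baseline-subtracted mean rate in a response window (Hz)."""
    t = spikes.times_s if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    events = np.asarray(events, dtype=float)
    if events.size == 0 or window[1] <= window[0] or baseline_window[1] <= baseline_window[0]:
        raise ValueError("windows and events must be non-empty")
    return _window_rate(t, events, window) - _window_rate(t, events, baseline_window)


@dataclass
class PeakResult:
    peak_hz: float | None
    fdhm_ms: float | None
    truncated: bool = False


def peak_and_fdhm(psth: PSTH, window: tuple[float, float]) -> PeakResult:
    """Largest peak in the window and its full duration at half maximum.

    Half-max crossings are found by scanning outward from the peak with
    linear interpolation between 1 ms bins; if a crossing leaves the
    window, the window edge bounds the width and the result is flagged
    ``truncated``.  An all-zero (or non-positive) PSTH in the window has
    no peak: both values are reported missing.
    """
    sel = (psth.bin_centers_s >= window[0]) & (psth.bin_centers_s <= window[1])
    if not np.any(sel):
        raise ValueError("window lies outside the PSTH support")
    r = psth.rate_hz[sel]
    x = psth.bin_centers_s[sel]
    k = int(np.argmax(r))
    peak = float(r[k])
    if peak <= 0:
        return PeakResult(None, None)
    half = peak / 2.0

    def cross(direction):
        i = k
        while 0 <= i + direction < len(r):
            j = i + direction
            if r[j] < half:
                # linear interpolation between bins i and j
                frac = (r[i] - half) / (r[i] - r[j])
                return x[i] + frac * (x[j] - x[i]), False
            i = j
        return x[-1] if direction > 0 else x[0], True

    left, trunc_l = cross(-1)
    right, trunc_r = cross(+1)
    return PeakResult(peak, float((right - left) * 1000.0), trunc_l or trunc_r)


def omission_significance(
    per_trial_baseline_hz,
    per_trial_omission_hz,
    alpha: float = 0.05,
):
    """Classify an omission pause from paired per-trial rates.

    Returns ``(significant_pause, p_value, mean_difference_hz)``: a pause
    requires the paired t-test to reject at ``alpha`` and the mean
    (omission − baseline) difference to be negative.  Zero-variance
    differences carry no evidence and classify as not significant.
    """
    base = np.asarray(per_trial_baseline_hz, float)
    om = np.asarray(per_trial_omission_hz, float)
    if base.shape != om.shape or base.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    diff = om - base
    mean_diff = float(diff.mean())
    if np.allclose(diff, diff[0]):
        warnings.warn(
            "zero variance of paired differences; classifying as not significant",
            stacklevel=2,
        )
        return False, float("nan"), mean_diff
    stat = ttest_rel(om, base)
    p = float(stat.pvalue)
    return bool(p < alpha and mean_diff < 0), p, mean_diff
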