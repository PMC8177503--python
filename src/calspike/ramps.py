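"""Position-ramp analysis of firing in a virtual linear maze (−30 to 290 cm).

Rates by position are spike counts divided by occupancy time, in
non-overlapping 10 cm bins (or a 10 cm window moved at 1 cm steps for
smooth profiles).  The linear ramp magnitude is the ordinary
least-squares slope of the binned rate on bin-center position, scaled by
the 290 cm maze length.  Ramp *classification* uses a logistic GLM on
per-timestep spike indicators,

    logit p = β₀ + β₁·position + Σᵢ βᵢ·1(trial i),

with reference-coded trial factors; a neuron ramps up/down when the
position coefficient is significant at α = 0.01, with the direction given
by its sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import SpikeTrain

__all__ = [
    "RampFit",
    "position_binned_rate",
    "moving_average_rate",
    "ramp_linear_change",
    "ramp_glm_classify",
]

MAZE_EDGES_CM = (-30.0, 290.0)
#: scale for converting a per-cm coefficient into a whole-maze change
MAZE_LENGTH_CM = 290.0


@dataclass
class RampFit:
    position_coefficient: float  # log-odds per cm (GLM beta1)
    glm_p_value: float
    classification: str  # "up" | "down" | "none"
    linear_change_hz: float | None = None
    slope_hz_per_cm: float | None = None


def _spike_bins(spikes, track):
    """Bin index (by nearest track sample) for each spike; -1 if outside."""
    t = spikes.times_s if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    tt = track["time_s"].to_numpy()
    pos = track["position_cm"].to_numpy()
    # nearest-time interpolation of position onto spike times
    j = np.clip(np.searchsorted(tt, t), 0, len(tt) - 1)
    j_prev = np.clip(j - 1, 0, len(tt) - 1)
    use_prev = np.abs(tt[j_prev] - t) <= np.abs(tt[j] - t)
    return pos[np.where(use_prev, j_prev, j)]


def position_binned_rate(
    spikes,
    track: pd.DataFrame,
    bin_cm: float = 10.0,
    edges_cm: tuple[float, float] = MAZE_EDGES_CM,
):
    """Firing rate per non-overlapping position bin.

    Occupancy per bin is the summed sample spacing of track samples in
    the bin; the rate is (spikes while in the bin)/(occupancy time).
    Never-visited bins are missing (NaN), not zero.  Returns
    ``(bin_centers_cm, rates_hz, occupancy_s)``.
    """
    if track is None or len(track) == 0:
        raise ValueError("empty position track")
    edges = np.arange(edges_cm[0], edges_cm[1] + bin_cm / 2, bin_cm)
    centers = (edges[:-1] + edges[1:]) / 2
    tt = track["time_s"].to_numpy()
    pos = track["position_cm"].to_numpy()
    dt = np.empty_like(tt)
    dt[:-1] = np.diff(tt)
    dt[-1] = dt[-2] if len(tt) > 1 else 0.0
    # trial boundaries produce huge dt; clip to the median sample spacing
    med = np.median(dt[:-1]) if len(tt) > 1 else 0.0
    dt = np.clip(dt, 0.0, 2 * med if med > 0 else None)

    which = np.digitize(pos, edges) - 1
    which = np.clip(which, 0, len(centers) - 1)
    occupancy = np.bincount(which, weights=dt, minlength=len(centers))

    spike_pos = _spike_bins(spikes, track)
    sbin = np.digitize(spike_pos, edges) - 1
    sbin = sbin[(sbin >= 0) & (sbin < len(centers))]
    counts = np.bincount(sbin, minlength=len(centers))

    rates = np.where(occupancy > 0, counts / np.where(occupancy > 0, occupancy, 1), np.nan)
    return centers, rates, occupancy


def moving_average_rate(
    spikes,
    track: pd.DataFrame,
    window_cm: float = 10.0,
    step_cm: float = 1.0,
    edges_cm: tuple[float, float] = MAZE_EDGES_CM,
):
    """Sliding-window analogue of :func:`position_binned_rate`.

    A ``window_cm`` window is moved in ``step_cm`` increments; windows
    with zero occupancy are missing.  Returns ``(centers_cm, rates_hz)``.
    """
    if track is None or len(track) == 0:
        raise ValueError("empty position track")
    tt = track["time_s"].to_numpy()
    pos = track["position_cm"].to_numpy()
    dt = np.empty_like(tt)
    dt[:-1] = np.diff(tt)
    dt[-1] = dt[-2] if len(tt) > 1 else 0.0
    med = np.median(dt[:-1]) if len(tt) > 1 else 0.0
    dt = np.clip(dt, 0.0, 2 * med if med > 0 else None)
    spike_pos = _spike_bins(spikes, track)

    starts = np.arange(edges_cm[0], edges_cm[1] - window_cm + step_cm / 2, step_cm)
    centers = starts + window_cm / 2
    rates = np.full(len(starts), np.nan)
    for i, s in enumerate(starts):
        occ = float(dt[(pos >= s) & (pos < s + window_cm)].sum())
        if occ > 0:
            n = int(np.sum((spike_pos >= s) & (spike_pos < s + window_cm)))
            rates[i] = n / occ
    return centers, rates


def ramp_linear_change(bin_centers_cm, rates_hz):
    """OLS slope of rate on position and the change over the maze.

    Missing bins are dropped; at least 3 non-missing bins are required.
    Returns ``(slope_hz_per_cm, linear_change_hz)`` with
    ``linear_change = slope × 290``.
    """
    x = np.asarray(bin_centers_cm, float)
    r = np.asarray(rates_hz, float)
    ok = np.isfinite(r)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing position bins")
    slope, _ = np.polyfit(x[ok], r[ok], 1)
    return float(slope), float(slope * MAZE_LENGTH_CM)


def ramp_glm_classify(
    spike_indicators,
    positions_cm,
    trial_ids,
    alpha: float = 0.01,
) -> RampFit:
    """Logistic-GLM ramp classification with trial factors.

    ``spike_indicators`` codes each timestep 1 if it contains at least
    one spike (the deconvolution emits at most one jump per timestep, so
    this is lossless at the native rate).  Trials enter as
    reference-coded indicator covariates (first trial is the reference).
    Non-convergence or complete separation yields classification
    ``none`` with a warning rather than an error.
    """
    yb = np.asarray(spike_indicators, float)
    x = np.asarray(positions_cm, float)
    tid = np.asarray(trial_ids)
    if not set(np.unique(yb)) <= {0.0, 1.0}:
        raise ValueError("spike indicators must be binary")
    if yb.sum() == 0:
        return RampFit(0.0, 1.0, "none")

    dummies = pd.get_dummies(pd.Series(tid), drop_first=True, dtype=float)
    X = np.column_stack([np.ones_like(x), x, dummies.to_numpy()])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(yb, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise RuntimeError("logit did not converge")
        beta1 = float(fit.params[1])
        p = float(fit.pvalues[1])
    except Exception as exc:  # separation / singular design / no convergence
        warnings.warn(f"ramp GLM degenerate ({exc}); classifying as none", stacklevel=2)
        return RampFit(0.0, 1.0, "none")
    if not np.isfinite(p):
        return RampFit(beta1, 1.0, "none")
    cls = "none"
    if p < alpha:
        cls = "up" if beta1 > 0 else "down"
    return RampFit(beta1, p, cls)
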