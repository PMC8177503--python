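"""Fluorescence preprocessing: neuropil correction, ΔF/F, detrend, resample.

The fixed pipeline order is neuropil correction → rolling-percentile ΔF/F →
robust detrend with percentile rescale → Fourier upsampling by two.  The
stages mirror common practice for one-photon/two-photon somatic traces:

1. ``neuropil_correct``: F_corr = F_raw − Υ·F_annulus (Υ = 0.58 for the
   in vivo preset, 1.0 in vitro).
2. ``rolling_baseline_dff``: baseline F⁰ₜ is the 8th percentile of the
   trailing 60 s window; ΔF/F = (F − F⁰)/F⁰.  This stage is lossy (the
   absolute scale is discarded).
3. ``robust_detrend_rescale``: residuals of a robust linear regression on
   time with two-component Gaussian-mixture errors, then shifted by their
   1st percentile and scaled by the 80th−1st percentile difference.  Lossy.
4. ``resample_double``: band-limited (Fourier) resampling to twice the
   length, e.g. 33.33 → 66.67 Hz, so that more than one spike can land in
   an original frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import resample

from .core import FluorescenceTrace

__all__ = [
    "PreprocessParams",
    "INVITRO",
    "INVIVO",
    "neuropil_correct",
    "rolling_baseline_dff",
    "robust_detrend_rescale",
    "resample_double",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class PreprocessParams:
    neuropil_factor: float = 1.0
    baseline_window_s: float = 60.0
    baseline_percentile: float = 8.0
    rescale_low_pct: float = 1.0
    rescale_high_pct: float = 80.0
    resample_factor: int = 2

    def __post_init__(self) -> None:
        if self.neuropil_factor < 0:
            raise ValueError("neuropil factor must be non-negative")
        if not 0 < self.baseline_percentile < 100:
            raise ValueError("baseline percentile must be in (0, 100)")
        if not self.rescale_low_pct < self.rescale_high_pct:
            raise ValueError("rescale percentiles must be ordered")


INVITRO = PreprocessParams(neuropil_factor=1.0)
INVIVO = PreprocessParams(neuropil_factor=0.58)


def neuropil_correct(
    f_raw: FluorescenceTrace, f_annulus: FluorescenceTrace, factor: float
) -> FluorescenceTrace:
    """Subtract scaled annulus fluorescence: F_corr = F_raw − factor·F_annulus."""
    if len(f_raw) != len(f_annulus):
        raise ValueError(
            f"trace lengths differ: ROI has {len(f_raw)} samples, annulus {len(f_annulus)}"
        )
    if f_raw.sampling_rate_hz != f_annulus.sampling_rate_hz:
        raise ValueError("sampling rates differ between ROI and annulus traces")
    return replace(f_raw, values=f_raw.values - factor * f_annulus.values)


def rolling_baseline_dff(
    f: FluorescenceTrace, params: PreprocessParams = PreprocessParams()
) -> FluorescenceTrace:
    """ΔF/F against a trailing low-percentile baseline.

    The baseline at sample ``t`` is the ``baseline_percentile`` of the
    trailing window ``F_{t−L} … F_t`` with ``L = baseline_window_s ×
    rate`` (linear interpolation between order statistics).  At the start
    of the recording, where fewer than L+1 samples exist, all available
    samples are used.
    """
    window = int(round(params.baseline_window_s * f.sampling_rate_hz)) + 1
    if window < 2:
        raise ValueError("baseline window must cover at least one sample lag")
    baseline = (
        pd.Series(f.values)
        .rolling(window=window, min_periods=1)
        .quantile(params.baseline_percentile / 100.0, interpolation="linear")
        .to_numpy()
    )
    if np.any(baseline <= 0):
        bad = int(np.flatnonzero(baseline <= 0)[0])
        raise ValueError(
            f"baseline is non-positive at index {bad}; ΔF/F undefined "
            "(raw fluorescence must stay positive)"
        )
    return replace(f, values=(f.values - baseline) / baseline)


def _em_mixture_regression(t, g, n_iter=200, rtol=1e-8):
    """Robust line fit with two-component Gaussian mixture errors.

    Both components share the regression line and differ in variance; the
    low-variance component dominates the fit, down-weighting outliers.
    Fit by EM from an ordinary least-squares start; returns (intercept,
    slope).
    """
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, g, rcond=None)
    resid = g - X @ beta
    s2 = float(np.var(resid)) or 1e-12
    var = np.array([0.5 * s2, 2.0 * s2])
    pi = np.array([0.5, 0.5])
    ll_old = -np.inf
    for _ in range(n_iter):
        # E-step: responsibilities under the two shared-mean Gaussians
        log_p = (
            np.log(pi)[None, :]
            - 0.5 * np.log(2 * np.pi * var)[None, :]
            - 0.5 * resid[:, None] ** 2 / var[None, :]
        )
        m = log_p.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_p - m).sum(axis=1))
        r = np.exp(log_p - lse[:, None])
        ll = float(lse.sum())
        # M-step: precision-weighted least squares, then variances/weights
        w = (r / var[None, :]).sum(axis=1)
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ g)
        resid = g - X @ beta
        nk = r.sum(axis=0)
        var = np.maximum((r * resid[:, None] ** 2).sum(axis=0) / nk, 1e-14)
        pi = nk / len(g)
        if abs(ll - ll_old) <= rtol * (abs(ll_old) + 1e-12):
            break
        ll_old = ll
    return float(beta[0]), float(beta[1])


def robust_detrend_rescale(
    g: FluorescenceTrace, params: PreprocessParams = PreprocessParams()
) -> FluorescenceTrace:
    """Remove a linear trend robustly and rescale to percentile units.

    Residuals of the mixture-error regression of ΔF/F on time are shifted
    by their 1st percentile and divided by the (80th − 1st) percentile
    difference, so the output's 1st percentile is 0 and 80th is 1.
    """
    if len(g) < 10:
        raise ValueError("need at least 10 samples to detrend")
    t = g.times_s
    b0, b1 = _em_mixture_regression(t, g.values)
    resid = g.values - (b0 + b1 * t)
    lo = np.percentile(resid, params.rescale_low_pct)
    hi = np.percentile(resid, params.rescale_high_pct)
    if hi - lo <= 0:
        raise ValueError("degenerate rescale: high and low percentiles coincide")
    return replace(g, values=(resid - lo) / (hi - lo))


def resample_double(g: FluorescenceTrace) -> FluorescenceTrace:
    """Fourier-method resampling to exactly 2N samples (rate doubled)."""
    if len(g) < 2:
        raise ValueError("need at least 2 samples to resample")
    out = resample(g.values, 2 * len(g))
    return FluorescenceTrace(out, 2 * g.sampling_rate_hz, g.start_time_s)


def preprocess_pipeline(
    f_raw: FluorescenceTrace,
    f_annulus: FluorescenceTrace | None = None,
    params: PreprocessParams = INVITRO,
) -> FluorescenceTrace:
    """Run the full fixed-order pipeline; the result is the trace y_t."""
    f = f_raw
    if f_annulus is not None:
        f = neuropil_correct(f, f_annulus, params.neuropil_factor)
    g = rolling_baseline_dff(f, params)
    g = robust_detrend_rescale(g, params)
    for _ in range(int(np.log2(params.resample_factor))):
        g = resample_double(g)
    return g
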