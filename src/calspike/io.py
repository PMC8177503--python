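"""Delimited-table I/O for traces, spike trains, events and position tracks.

All tables are comma-delimited text with a one-line header:

* trace table    — ``time_s, f_raw`` (optional ``f_annulus``)
* spike table    — ``spike_time_s`` (optional ``jump_size``)
* event table    — ``trial_id, event_type, time_s``
* track table    — ``time_s, position_cm, trial_id``

Simulation configs are echoed as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import FluorescenceTrace, SpikeTrain

EVENT_TYPES = ("cue_onset", "reward", "unexpected_reward", "omission_onset")


def write_trace(path, trace: FluorescenceTrace, annulus: FluorescenceTrace | None = None) -> None:
    cols = {"time_s": trace.times_s, "f_raw": trace.values}
    if annulus is not None:
        if len(annulus) != len(trace):
            raise ValueError("annulus length does not match trace")
        cols["f_annulus"] = annulus.values
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trace(path, sampling_rate_hz: float | None = None) -> FluorescenceTrace:
    """Read a trace table; the rate is inferred from time stamps if not given."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if sampling_rate_hz is None:
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from a single sample")
        sampling_rate_hz = 1.0 / float(np.median(np.diff(t)))
    return FluorescenceTrace(df["f_raw"].to_numpy(), sampling_rate_hz, float(t[0]))


def read_annulus(path, sampling_rate_hz: float | None = None) -> FluorescenceTrace | None:
    df = pd.read_csv(path)
    if "f_annulus" not in df.columns:
        return None
    t = df["time_s"].to_numpy()
    if sampling_rate_hz is None:
        sampling_rate_hz = 1.0 / float(np.median(np.diff(t)))
    return FluorescenceTrace(df["f_annulus"].to_numpy(), sampling_rate_hz, float(t[0]))


def write_spikes(path, spikes: SpikeTrain, jump_sizes=None) -> None:
    cols = {"spike_time_s": spikes.times_s}
    if jump_sizes is not None:
        cols["jump_size"] = np.asarray(jump_sizes, dtype=float)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_spikes(path, duration_s: float | None = None) -> SpikeTrain:
    df = pd.read_csv(path)
    t = np.sort(df["spike_time_s"].to_numpy(dtype=float))
    if duration_s is None:
        duration_s = float(t[-1]) if len(t) else 0.0
    return SpikeTrain(t, duration_s)


def write_events(path, events: pd.DataFrame) -> None:
    events[["trial_id", "event_type", "time_s"]].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    bad = set(df["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise ValueError(f"unknown event types: {sorted(bad)}")
    return df


def write_track(path, track: pd.DataFrame) -> None:
    track[["time_s", "position_cm", "trial_id"]].to_csv(path, index=False)


def read_track(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_config(path, config) -> None:
    from dataclasses import asdict, is_dataclass

    obj = asdict(config) if is_dataclass(config) else dict(config)
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
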