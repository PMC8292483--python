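"""Fiber-photometry analysis: dF/F, event-triggered averages,
onset-lead estimation, and evoked-transient input-output curves.

Fluorescence traces are sampled at 100 Hz (hardware low-pass at 40 Hz).
dF/F is computed against a running low-percentile baseline (10th
percentile over a 30-s window by default), which tracks slow bleaching
while ignoring transients; a fixed global-percentile baseline is also
available.  dF/F is exactly invariant to multiplying the raw trace by a
positive gain.

Evoked responses to single light pulses are summarized by their
amplitude: the peak of the pulse-averaged dF/F in a 1-s post-pulse
window minus the 1-s pre-pulse mean.  Optional boxcar smoothing of the
average before the peak is available for noisy single-pulse data but
off by default, keeping the estimator exactly unbiased on noiseless
input.  Amplitudes across laser powers form the input-output curve;
dopamine-receptor antagonist experiments are summarized by the ratio of
mean evoked amplitude, treated over control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AlignedResponse, OnsetOffsetEstimate, detect_onset_offset

__all__ = [
    "FluorescenceTrace",
    "DFFTrace",
    "EvokedResponse",
    "compute_dff",
    "event_triggered_average",
    "onset_lead",
    "evoked_amplitude",
    "input_output_curve",
    "suppression_ratio",
]

DEFAULT_BASELINE_PERCENTILE = 10.0
DEFAULT_BASELINE_WINDOW_S = 30.0


@dataclass
class FluorescenceTrace:
    """Raw fluorescence at a uniform sample rate (100 Hz nominal)."""

    time: np.ndarray
    raw: np.ndarray
    channel: str = "sensor"  # "sensor" or "control"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.time.shape != self.raw.shape:
            raise ValueError("time and raw must have the same length")
        if len(self.time) < 2:
            raise ValueError("trace too short")
        dt = np.diff(self.time)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace must be uniformly sampled")
        if not np.all(np.isfinite(self.raw)):
            raise ValueError("raw trace contains non-finite values")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


@dataclass
class DFFTrace:
    time: np.ndarray
    dff: np.ndarray
    baseline_method: str = "running_percentile"
    channel: str = "sensor"

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


def compute_dff(
    trace: FluorescenceTrace,
    method: str = "running_percentile",
    percentile: float = DEFAULT_BASELINE_PERCENTILE,
    window_s: float = DEFAULT_BASELINE_WINDOW_S,
) -> DFFTrace:
    """dF/F = (F - F0) / F0 with a percentile baseline F0.

    ``method='running_percentile'`` (default): F0 is the centered
    rolling ``percentile`` of the raw trace over ``window_s``.
    ``method='global_percentile'``: a single percentile of the whole
    trace.  Raises when F0 is not strictly positive anywhere (the raw
    trace must be background-corrected upstream).
    """
    fs = trace.sample_rate
    if method == "running_percentile":
        win = max(3, int(round(window_s * fs)))
        if win >= len(trace.raw):
            win = len(trace.raw)
        f0 = (
            pd.Series(trace.raw)
            .rolling(win, center=True, min_periods=1)
            .quantile(percentile / 100.0)
            .to_numpy()
        )
    elif method == "global_percentile":
        f0 = np.full_like(trace.raw, np.percentile(trace.raw, percentile))
    else:
        raise ValueError(f"unknown baseline method: {method}")
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 <= 0; raw trace not background-corrected")
    return DFFTrace(
        time=trace.time.copy(),
        dff=(trace.raw - f0) / f0,
        baseline_method=method,
        channel=trace.channel,
    )


def event_triggered_average(
    dff: DFFTrace,
    events: np.ndarray,
    window: tuple[float, float] = (-1.0, 2.0),
    baseline_window: tuple[float, float] = (-1.0, -0.2),
) -> AlignedResponse:
    """Peri-event dF/F matrix and trial average on the native sample grid."""
    events = np.asarray(events, dtype=float)
    fs = dff.sample_rate
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    offsets = np.arange(i0, i1 + 1)
    centers = offsets / fs
    rows = []
    for ev in events:
        k = int(round((ev - dff.time[0]) * fs))
        if k + i0 < 0 or k + i1 >= len(dff.dff):
            continue
        rows.append(dff.dff[k + offsets])
    if not rows:
        raise ValueError("no event lies fully inside the trace")
    return AlignedResponse(
        time=centers,
        per_trial=np.asarray(rows),
        baseline_window=baseline_window,
        kind="dff",
    )


def onset_lead(avg: AlignedResponse, **kwargs) -> OnsetOffsetEstimate:
    """Onset of the event-triggered average by the 15%-of-peak rule.

    Negative onset times mean the fluorescence rise *leads* the event
    (e.g. dopamine transients preceding locomotion initiation).
    """
    return detect_onset_offset(avg, **kwargs)


@dataclass(frozen=True)
class EvokedResponse:
    stimulus_power: float  # mW
    amplitude: float  # peak post-pulse dF/F minus pre-pulse mean
    n_pulses: int
    channel: str = "sensor"


def evoked_amplitude(
    dff: DFFTrace,
    pulse_times: np.ndarray,
    power: float,
    pre_window: tuple[float, float] = (-1.0, 0.0),
    post_window: tuple[float, float] = (0.0, 1.0),
    smooth_s: float = 0.0,
) -> EvokedResponse:
    """Pulse-averaged evoked amplitude at one laser power.

    The dF/F segments around the pulses are averaged; the amplitude is
    the maximum of the average within ``post_window`` minus its mean
    within ``pre_window``.  ``smooth_s`` applies an optional boxcar to
    the average first (off by default: exact on noiseless input).
    """
    avg = event_triggered_average(
        dff, pulse_times, window=(pre_window[0], post_window[1]),
        baseline_window=pre_window,
    )
    y = avg.mean
    if smooth_s and smooth_s > 0:
        k = max(1, int(round(smooth_s * dff.sample_rate)))
        y = np.convolve(y, np.ones(k) / k, mode="same")
    pre = (avg.time >= pre_window[0]) & (avg.time < pre_window[1])
    post = (avg.time >= post_window[0]) & (avg.time <= post_window[1])
    amp = float(np.max(y[post]) - np.mean(y[pre]))
    return EvokedResponse(
        stimulus_power=float(power),
        amplitude=amp,
        n_pulses=avg.n_events,
        channel=dff.channel,
    )


def input_output_curve(responses: Sequence[EvokedResponse]) -> pd.DataFrame:
    """Mean evoked amplitude (+/- SEM) per laser power, sorted by power.

    Control-channel responses may be mixed in; the table is grouped by
    (channel, power) so sensor and control curves sit side by side.
    """
    if len({(r.channel, r.stimulus_power) for r in responses}) < 2:
        raise ValueError("need at least two distinct powers or channels")
    df = pd.DataFrame(
        {
            "channel": [r.channel for r in responses],
            "power_mw": [r.stimulus_power for r in responses],
            "amplitude": [r.amplitude for r in responses],
        }
    )
    out = (
        df.groupby(["channel", "power_mw"])["amplitude"]
        .agg(mean_amplitude="mean", sem="sem", n="count")
        .reset_index()
        .sort_values(["channel", "power_mw"], ignore_index=True)
    )
    return out


def suppression_ratio(
    treated: Sequence[EvokedResponse], control: Sequence[EvokedResponse]
) -> float:
    """Mean treated evoked amplitude divided by mean control amplitude.

    Quantifies pharmacological suppression of the evoked transient
    (e.g. D2-antagonist treatment vs saline); 1.0 means no suppression.
    """
    if not treated or not control:
        raise ValueError("both groups must be non-empty")
    mc = float(np.mean([r.amplitude for r in control]))
    if mc == 0:
        raise ValueError("control amplitude is zero; ratio undefined")
    return float(np.mean([r.amplitude for r in treated])) / mc
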