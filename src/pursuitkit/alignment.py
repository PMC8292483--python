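"""Peri-event alignment shared by spike and photometry analyses.

:class:`AlignedResponse` holds a trial x time matrix of a signal
(firing rate in Hz, or dF/F) on a common peri-event time base, its
trial average, and a Z-scored average computed against a baseline
window.  :func:`detect_onset_offset` implements the 15%-of-peak rule
used to time responses relative to the event: the response onset is the
first time before the peak at which the (optionally smoothed) signal
crosses baseline + 0.15 * (peak - baseline) and stays above threshold,
with sub-bin linear interpolation of the crossing.  Negative onset
times mean the signal leads the event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = ["AlignedResponse", "OnsetOffsetEstimate", "detect_onset_offset"]

#: fraction of peak amplitude defining response onset/offset
ONSET_THRESHOLD_FRACTION = 0.15
#: bins the signal must hold beyond threshold to accept a crossing
DEFAULT_HOLD_BINS = 3


@dataclass
class AlignedResponse:
    """Trial-aligned signal on a peri-event time grid.

    ``per_trial`` has shape (n_events, n_bins); ``time`` holds bin
    centers in seconds relative to the event.  ``zscored`` is the trial
    average Z-scored against the mean/SD of the average over
    ``baseline_window``; it is None (with ``baseline_degenerate`` set)
    when the baseline SD is zero.
    """

    time: np.ndarray
    per_trial: np.ndarray
    baseline_window: tuple[float, float]
    kind: str = "rate"  # "rate" (Hz) or "dff"
    mean: np.ndarray = field(init=False)
    zscored: np.ndarray | None = field(init=False)
    baseline_degenerate: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.per_trial = np.atleast_2d(np.asarray(self.per_trial, dtype=float))
        if self.per_trial.shape[1] != len(self.time):
            raise ValueError("per_trial and time length mismatch")
        self.mean = self.per_trial.mean(axis=0)
        b0, b1 = self.baseline_window
        in_base = (self.time >= b0) & (self.time < b1)
        if not in_base.any():
            raise ValueError("baseline window outside peri-event time base")
        base = self.mean[in_base]
        sd = float(np.std(base, ddof=1)) if base.size > 1 else 0.0
        if sd == 0.0 or not np.isfinite(sd):
            self.zscored = None
            self.baseline_degenerate = True
        else:
            self.zscored = (self.mean - float(np.mean(base))) / sd

    @property
    def n_events(self) -> int:
        return self.per_trial.shape[0]

    @property
    def bin_s(self) -> float:
        return float(self.time[1] - self.time[0])

    def signal(self) -> np.ndarray:
        """Z-scored average when defined, raw average otherwise."""
        return self.mean if self.zscored is None else self.zscored


@dataclass(frozen=True)
class OnsetOffsetEstimate:
    onset_time: float | None
    offset_time: float | None
    threshold_fraction: float = ONSET_THRESHOLD_FRACTION


def _first_sustained_crossing(
    t: np.ndarray,
    y: np.ndarray,
    threshold: float,
    peak_idx: int,
    hold_bins: int,
    upward: bool,
) -> float | None:
    """Interpolated time of the first threshold crossing, searched up to the
    peak (upward) or from the peak on (downward), that holds for
    ``hold_bins`` bins (runs truncated by the series end count as held)."""
    sign = 1.0 if upward else -1.0
    beyond = sign * y >= sign * threshold
    search = range(peak_idx + 1) if upward else range(peak_idx, len(t))
    for k in search:
        if not beyond[k]:
            continue
        run = beyond[k : k + hold_bins]
        if not run.all():
            continue
        if k == 0 or beyond[k - 1]:
            # beyond from the very start of the search: no crossing to
            # interpolate, report the first held bin
            return float(t[k])
        y0, y1 = y[k - 1], y[k]
        if y1 == y0:
            return float(t[k])
        frac = (threshold - y0) / (y1 - y0)
        return float(t[k - 1] + frac * (t[k] - t[k - 1]))
    return None


def detect_onset_offset(
    resp: AlignedResponse,
    threshold_fraction: float = ONSET_THRESHOLD_FRACTION,
    smooth_sigma: float | None = None,
    hold_bins: int = DEFAULT_HOLD_BINS,
    peak_window: tuple[float, float] | None = None,
) -> OnsetOffsetEstimate:
    """Time the response onset/offset by the 15%-of-peak rule.

    Parameters
    ----------
    resp:
        Aligned response; the Z-scored average is used when defined.
    threshold_fraction:
        Fraction of (peak - baseline) defining the threshold (0.15).
    smooth_sigma:
        Optional Gaussian smoothing of the signal, in seconds.  Off by
        default so piecewise-linear inputs reproduce the analytic
        crossing exactly; spike PSTHs typically pass 0.05.
    hold_bins:
        Crossings must hold beyond threshold this many bins.
    peak_window:
        Time window searched for the peak; defaults to everything after
        the baseline window.

    Returns an estimate with ``onset_time``/``offset_time`` None when
    the response never exceeds baseline.
    """
    y = resp.signal().astype(float)
    t = resp.time
    if smooth_sigma is not None and smooth_sigma > 0:
        y = gaussian_filter1d(y, sigma=smooth_sigma / resp.bin_s, mode="nearest")
    b0, b1 = resp.baseline_window
    in_base = (t >= b0) & (t < b1)
    baseline = float(np.mean(y[in_base]))
    if peak_window is None:
        peak_window = (b1, float(t[-1]))
    in_peak = (t >= peak_window[0]) & (t <= peak_window[1])
    if not in_peak.any():
        raise ValueError("empty peak search window")
    seg = np.where(in_peak, y, -np.inf)
    peak_idx = int(np.argmax(seg))
    peak = float(y[peak_idx])
    if peak <= baseline:
        return OnsetOffsetEstimate(None, None, threshold_fraction)
    threshold = baseline + threshold_fraction * (peak - baseline)
    onset = _first_sustained_crossing(t, y, threshold, peak_idx, hold_bins, upward=True)
    offset = _first_sustained_crossing(t, y, threshold, peak_idx, hold_bins, upward=False)
    return OnsetOffsetEstimate(onset, offset, threshold_fraction)
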