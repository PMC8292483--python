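"""Approach-episode segmentation and hunting metrics.

An *approach episode* is an interval of appetitive locomotion in which
the predator closes on the prey.  Two empirical criteria define it:

1. the predator-prey distance (PPD) decreases essentially monotonically
   until it drops below the capture distance (3 cm), and
2. the head-to-prey azimuth angle stays within -90..+90 deg throughout.

Tracking jitter would shatter episodes under a literal monotonicity
requirement, so "decreasing" is implemented as a running-minimum rule:
within an episode no sample may exceed the running PPD minimum by more
than ``jitter_tol`` (0.5 cm by default).  The detector scans the series
once; an independent brute-force implementation of the same definition
lives in the test suite and the two are held exactly equal.

Five per-trial metrics quantify hunting (all defined from the attack
log and the detected episodes):

* time to capture  = last jaw attack - prey introduction
* latency to attack = first jaw attack - prey introduction
* attack frequency  = number of attacks / time to capture
* approach speed    = mean over episodes of the peak binned speed
* approach frequency = number of episodes / time to capture

Metrics that are undefined (no attacks, no episodes) are reported as
``None``, never as 0 - zero is a valid frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np

from .kinematics import KinematicSeries

__all__ = [
    "ApproachEpisode",
    "AttackLog",
    "HuntingTrialResult",
    "NetEffect",
    "detect_approach_episodes",
    "approach_speed",
    "approach_frequency",
    "attack_metrics",
    "net_effect",
    "average_per_mouse",
    "ethogram_labels",
]

#: PPD threshold (cm) the approach must reach ("until it is less than 3 cm")
CAPTURE_PPD_CM = 3.0
#: tolerated transient PPD rise above the running minimum (cm)
DEFAULT_JITTER_TOL_CM = 0.5
#: azimuth criterion half-width (deg)
AZIMUTH_LIMIT_DEG = 90.0
#: episodes closer than this merge (s)
DEFAULT_MIN_GAP_S = 0.5
#: episodes shorter than this are discarded (s) - one speed bin
DEFAULT_MIN_DURATION_S = 0.2


@dataclass(frozen=True)
class ApproachEpisode:
    start_time: float
    end_time: float
    peak_speed: float
    min_ppd: float

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class AttackLog:
    """Times of predatory jaw attacks plus the prey-introduction time."""

    attack_times: np.ndarray
    prey_intro_time: float = 0.0

    def __post_init__(self) -> None:
        self.attack_times = np.asarray(self.attack_times, dtype=float)
        if np.any(np.diff(self.attack_times) < 0):
            raise ValueError("attack times must be sorted")
        if len(self.attack_times) and self.attack_times[0] < self.prey_intro_time:
            raise ValueError("attacks cannot precede prey introduction")


@dataclass
class HuntingTrialResult:
    time_to_capture: float | None
    latency_to_attack: float | None
    attack_frequency: float | None
    approach_speed: float | None
    approach_frequency: float | None
    episodes: list[ApproachEpisode] = field(default_factory=list)
    n_defined: dict = field(default_factory=dict)

    _METRICS = (
        "time_to_capture",
        "latency_to_attack",
        "attack_frequency",
        "approach_speed",
        "approach_frequency",
    )


@dataclass(frozen=True)
class NetEffect:
    """Paired laser ON minus laser OFF effect on a metric."""

    metric_on: float
    metric_off: float

    @property
    def net(self) -> float:
        return self.metric_on - self.metric_off


def _episode_scan(
    ppd: np.ndarray,
    az_ok: np.ndarray,
    capture_ppd: float,
    jitter_tol: float,
) -> list[tuple[int, int]]:
    """Single left-to-right scan producing raw (start, end) index pairs.

    End candidates are the first frames where PPD crosses below the
    capture distance.  Each is extended backward as far as both criteria
    allow (running-minimum rule, azimuth mask, no missing PPD), and the
    start is then placed at the last frame attaining the extension's PPD
    maximum (the latest local maximum preceding the descent).
    """
    n = len(ppd)
    finite = np.isfinite(ppd)
    episodes: list[tuple[int, int]] = []
    last_end = -1
    e = 0
    while e < n:
        is_candidate = (
            finite[e]
            and ppd[e] < capture_ppd
            and az_ok[e]
            and e > last_end
            and e > 0
            and finite[e - 1]
            and ppd[e - 1] >= capture_ppd
        )
        if not is_candidate:
            e += 1
            continue
        # backward maximal extension: smallest i such that all frames in
        # [i, e] are az-ok, finite, and obey the running-minimum rule.
        # Prepending frame j lowers running minima only where ppd[j] is
        # below every value between j and a later sample, so the rule can
        # newly fail only for samples after j that exceed ppd[j] + tol
        # before any sample <= ppd[j] intervenes.
        i = e
        vals = [ppd[e]]  # ppd over [i, e], stored in e -> i order
        while i - 1 > last_end and az_ok[i - 1] and finite[i - 1]:
            v = ppd[i - 1]
            if _max_above_new_min(vals, v) - v > jitter_tol:
                break
            vals.append(v)
            i -= 1
        seg = ppd[i : e + 1]
        start = i + int(np.flatnonzero(seg == seg.max())[-1])
        episodes.append((start, e))
        last_end = e
        e += 1
    return episodes


def _max_above_new_min(vals: list, v: float) -> float:
    """Max of the values (stored e->i order) that a new minimum v constrains.

    A value ppd[k] is constrained by the new prefix minimum v only if no
    value between the new start and k is smaller than v (otherwise its
    running min is unchanged and was already checked).  Walking the stored
    suffix from the new start forward (list end -> front), stop at the
    first value <= v.
    """
    best = v
    for u in reversed(vals):
        if u <= v:
            break
        if u > best:
            best = u
    return best


def _postprocess(
    raw: list[tuple[int, int]],
    kin: KinematicSeries,
    az_ok: np.ndarray,
    min_gap: float,
    min_duration: float,
) -> list[ApproachEpisode]:
    """Merge episodes separated by < min_gap (only across frames that keep
    the azimuth criterion), drop ones shorter than min_duration, and
    attach peak speed / min PPD."""
    t = kin.time
    finite = np.isfinite(kin.ppd)
    merged: list[list[int]] = []
    for s, e in raw:
        if (
            merged
            and t[s] - t[merged[-1][1]] < min_gap
            and np.all(az_ok[merged[-1][1] : s + 1])
            and np.all(finite[merged[-1][1] : s + 1])
        ):
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if t[e] - t[s] < min_duration:
            continue
        speeds = kin.speed[s : e + 1]
        peak = float(np.nanmax(speeds)) if np.isfinite(speeds).any() else float("nan")
        out.append(
            ApproachEpisode(
                start_time=float(t[s]),
                end_time=float(t[e]),
                peak_speed=peak,
                min_ppd=float(np.nanmin(kin.ppd[s : e + 1])),
            )
        )
    return out


def detect_approach_episodes(
    kin: KinematicSeries,
    capture_ppd: float = CAPTURE_PPD_CM,
    jitter_tol: float = DEFAULT_JITTER_TOL_CM,
    azimuth_limit: float = AZIMUTH_LIMIT_DEG,
    min_gap: float = DEFAULT_MIN_GAP_S,
    min_duration: float = DEFAULT_MIN_DURATION_S,
) -> list[ApproachEpisode]:
    """Segment approach episodes from a kinematic series.

    See the module docstring for the two criteria and their numeric
    tolerances.  Returns non-overlapping episodes in temporal order.
    """
    if kin.ppd is None or kin.azimuth is None:
        raise ValueError("episode detection requires ppd and azimuth series")
    if not (np.isfinite(kin.ppd).any() and np.isfinite(kin.azimuth).any()):
        warnings.warn("all PPD/azimuth samples missing; no episodes detected")
        return []
    az_ok = np.abs(kin.azimuth) <= azimuth_limit
    az_ok &= np.isfinite(kin.azimuth)
    raw = _episode_scan(np.asarray(kin.ppd, float), az_ok, capture_ppd, jitter_tol)
    return _postprocess(raw, kin, az_ok, min_gap, min_duration)


def approach_speed(episodes: Sequence[ApproachEpisode]) -> float | None:
    """Mean of per-episode peak speeds (cm/s); None if no episodes."""
    if len(episodes) == 0:
        return None
    return float(np.mean([ep.peak_speed for ep in episodes]))


def approach_frequency(
    episodes: Sequence[ApproachEpisode], time_to_capture: float
) -> float:
    """Number of approach episodes divided by the time to prey capture."""
    if time_to_capture is None or time_to_capture <= 0:
        raise ValueError("time_to_capture must be positive")
    return len(episodes) / time_to_capture


def attack_metrics(
    attacks: AttackLog,
) -> tuple[float | None, float | None, float | None]:
    """(time_to_capture, latency_to_attack, attack_frequency) from the log.

    Capture time is last attack minus prey introduction; latency is first
    attack minus introduction; frequency is attack count over capture
    time.  All three are None when the log holds no attacks.
    """
    times = attacks.attack_times
    if len(times) == 0:
        return None, None, None
    capture = float(times[-1] - attacks.prey_intro_time)
    latency = float(times[0] - attacks.prey_intro_time)
    frequency = len(times) / capture if capture > 0 else None
    return capture, latency, frequency


def net_effect(on: float, off: float) -> NetEffect:
    """Net (laser ON minus laser OFF) change of a metric."""
    return NetEffect(metric_on=on, metric_off=off)


def hunting_trial_result(
    kin: KinematicSeries, attacks: AttackLog, **detect_kwargs
) -> HuntingTrialResult:
    """Full per-trial pipeline: episodes plus all five hunting metrics."""
    episodes = detect_approach_episodes(kin, **detect_kwargs)
    capture, latency, attack_freq = attack_metrics(attacks)
    return HuntingTrialResult(
        time_to_capture=capture,
        latency_to_attack=latency,
        attack_frequency=attack_freq,
        approach_speed=approach_speed(episodes),
        approach_frequency=(
            approach_frequency(episodes, capture) if capture else None
        ),
        episodes=episodes,
    )


def average_per_mouse(
    trial_results: Sequence[HuntingTrialResult],
) -> HuntingTrialResult:
    """Per-metric arithmetic mean over a mouse's trials.

    Undefined (None) metrics are skipped; the count of defined trials per
    metric is reported in ``n_defined``.  A metric undefined in every
    trial stays None.
    """
    if len(trial_results) == 0:
        raise ValueError("need at least one trial")
    means: dict[str, float | None] = {}
    counts: dict[str, int] = {}
    for name in HuntingTrialResult._METRICS:
        vals = [getattr(r, name) for r in trial_results]
        defined = [v for v in vals if v is not None]
        counts[name] = len(defined)
        means[name] = float(np.mean(defined)) if defined else None
    return HuntingTrialResult(episodes=[], n_defined=counts, **means)


def ethogram_labels(
    kin: KinematicSeries,
    episodes: Sequence[ApproachEpisode],
    attacks: AttackLog | None = None,
) -> "pd.DataFrame":
    """Per-frame ethogram table: label ('approach'/'other') and attack marks."""
    import pandas as pd

    label = np.full(len(kin.time), "other", dtype=object)
    for ep in episodes:
        inside = (kin.time >= ep.start_time) & (kin.time <= ep.end_time)
        label[inside] = "approach"
    attack = np.zeros(len(kin.time), dtype=bool)
    if attacks is not None and len(attacks.attack_times):
        dt = kin.time[1] - kin.time[0]
        idx = np.searchsorted(kin.time, attacks.attack_times)
        idx = np.clip(idx, 0, len(kin.time) - 1)
        attack[idx] = True
    return pd.DataFrame({"time": kin.time, "label": label, "attack": attack})
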