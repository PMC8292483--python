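"""Runway gait quantification and looming-escape metrics.

Gait: paw positions recorded from below a transparent runway alternate
between stance (paw planted, moving backward relative to the advancing
body) and swing (paw carried forward).  Stance onsets are detected as
downward sign changes of the paw's body-frame velocity along the
direction of travel, with a Schmitt-trigger hysteresis and a minimum
inter-step interval to reject jitter.  Step frequency is
(n_steps - 1) / (last - first stance onset); stride length is the mean
ground-frame displacement of the paw between consecutive stance onsets.

Looming escape: locomotion speed (200-ms bins) around three cycles of
an overhead expanding-disk stimulus is summarized by the peak speed
during the stimuli, and the average speeds before and after them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PawTraces",
    "GaitSummary",
    "LoomingSession",
    "EscapeMetrics",
    "detect_steps",
    "gait_summary",
    "escape_metrics",
]

PAW_LABELS = ("LF", "RF", "LH", "RH")

#: minimum interval between consecutive stance onsets (s)
MIN_STEP_INTERVAL_S = 0.1

#: default escape-metric windows (s): before = 10 s pre first stimulus,
#: during = first onset .. last onset + 2 s, after = 10 s post during-window
DEFAULT_BEFORE_S = 10.0
DEFAULT_DURING_TAIL_S = 2.0
DEFAULT_AFTER_S = 10.0


@dataclass
class PawTraces:
    """Positions of the four paws and the body centroid (cm, 50 Hz)."""

    time: np.ndarray
    paws: dict[str, np.ndarray]  # label -> (n, 2)
    body: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.body = np.asarray(self.body, dtype=float)
        n = len(self.time)
        if set(self.paws) != set(PAW_LABELS):
            raise ValueError(f"paw labels must be {PAW_LABELS}")
        self.paws = {k: np.asarray(v, dtype=float) for k, v in self.paws.items()}
        for k, v in self.paws.items():
            if v.shape != (n, 2):
                raise ValueError(f"paw {k} must have shape (n, 2)")
        if self.body.shape != (n, 2):
            raise ValueError("body must have shape (n, 2)")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


@dataclass
class GaitSummary:
    step_frequency: dict[str, float]  # Hz per paw (0 when no steps)
    stride_length: dict[str, float | None]  # cm per paw (None < 2 steps)
    fore_step_frequency: float | None = field(init=False)
    hind_step_frequency: float | None = field(init=False)
    fore_stride_length: float | None = field(init=False)
    hind_stride_length: float | None = field(init=False)

    def __post_init__(self) -> None:
        def agg(d, keys):
            vals = [d[k] for k in keys if d.get(k) is not None]
            return float(np.mean(vals)) if vals else None

        self.fore_step_frequency = agg(self.step_frequency, ("LF", "RF"))
        self.hind_step_frequency = agg(self.step_frequency, ("LH", "RH"))
        self.fore_stride_length = agg(self.stride_length, ("LF", "RF"))
        self.hind_stride_length = agg(self.stride_length, ("LH", "RH"))


def _travel_direction(body: np.ndarray) -> np.ndarray:
    d = body[-1] - body[0]
    norm = np.linalg.norm(d)
    if norm == 0:
        return np.array([1.0, 0.0])
    return d / norm


def detect_steps(
    paws: PawTraces,
    smooth_frames: int = 5,
    min_interval: float = MIN_STEP_INTERVAL_S,
) -> dict[str, np.ndarray]:
    """Stance-onset times per paw.

    Paw velocity is computed in the body frame, projected on the travel
    direction, and smoothed by a ``smooth_frames`` moving average.  A
    stance onset is a transition of this velocity from clearly positive
    (swing: paw carried forward) to clearly negative (stance: paw
    planted while the body advances), detected with a Schmitt trigger
    whose thresholds are +/- 25% of the velocity's robust amplitude.
    A stationary mouse yields zero steps for every paw.
    """
    dt = 1.0 / paws.frame_rate
    u = _travel_direction(paws.body)
    onsets: dict[str, np.ndarray] = {}
    for label in PAW_LABELS:
        rel = (paws.paws[label] - paws.body) @ u
        v = np.gradient(rel, dt)
        if smooth_frames > 1:
            kernel = np.ones(smooth_frames) / smooth_frames
            v = np.convolve(v, kernel, mode="same")
        amp = np.nanpercentile(np.abs(v), 90)
        if not np.isfinite(amp) or amp < 1e-9:
            onsets[label] = np.array([])
            continue
        h = 0.25 * amp
        times = []
        armed = False  # armed after v > +h (swing seen)
        last = -np.inf
        for i, vi in enumerate(v):
            if vi > h:
                armed = True
            elif armed and vi < -h:
                t = _refine_onset(paws.time, rel, i, smooth_frames)
                if t - last >= min_interval:
                    times.append(t)
                    last = t
                armed = False
        onsets[label] = np.asarray(times)
    return onsets


def _refine_onset(time: np.ndarray, rel: np.ndarray, i: int, smooth_frames: int) -> float:
    """Sub-frame stance-onset time at the swing->stance transition.

    The body-frame paw position peaks at the transition (rising during
    swing, falling during stance); its apex is localized by intersecting
    a line through two swing samples with a line through two stance
    samples, which is exact for noiseless piecewise-linear traces and
    removes the frame-grid quantization of the trigger sample ``i``.
    """
    j_lo = max(0, i - smooth_frames - 2)
    j_hi = min(len(rel) - 1, i + 2)
    j = j_lo + int(np.argmax(rel[j_lo : j_hi + 1]))
    if j - 2 < 0 or j + 2 >= len(rel):
        return float(time[j])
    s1 = (rel[j - 1] - rel[j - 2]) / (time[j - 1] - time[j - 2])
    s2 = (rel[j + 2] - rel[j + 1]) / (time[j + 2] - time[j + 1])
    denom = s1 - s2
    if not np.isfinite(denom) or denom <= 0:
        return float(time[j])
    a1 = rel[j - 1] - s1 * time[j - 1]
    a2 = rel[j + 1] - s2 * time[j + 1]
    t_star = (a2 - a1) / denom
    if not (time[j - 1] <= t_star <= time[j + 1]):
        return float(time[j])
    return float(t_star)


def gait_summary(steps: dict[str, np.ndarray], paws: PawTraces) -> GaitSummary:
    """Step frequency and stride length per paw from stance onsets.

    Frequency is (n - 1) / (t_last - t_first) over the paw's stance
    onsets (0 with fewer than 2 steps); stride length is the mean
    ground-frame displacement of the paw between consecutive onsets
    (None with fewer than 2 steps).
    """
    freq: dict[str, float] = {}
    stride: dict[str, float | None] = {}
    for label in PAW_LABELS:
        t = np.asarray(steps.get(label, []))
        if len(t) < 2:
            freq[label] = 0.0
            stride[label] = None
            continue
        freq[label] = float((len(t) - 1) / (t[-1] - t[0]))
        idx = np.searchsorted(paws.time, t)
        idx = np.clip(idx, 0, len(paws.time) - 1)
        pos = paws.paws[label][idx]
        disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        stride[label] = float(np.mean(disp))
    return GaitSummary(step_frequency=freq, stride_length=stride)


@dataclass
class LoomingSession:
    """Binned locomotion speed around three looming-stimulus cycles.

    ``stimulus_meta`` records the stimulus parameters (disk expansion
    2 deg -> 20 deg in 250 ms; background/disk luminances 3.6 and
    0.1 cd/m^2) for provenance; the metrics use only the onsets.
    """

    time: np.ndarray  # speed-bin start times (s)
    speed: np.ndarray  # cm/s per bin
    stimulus_onsets: np.ndarray
    stimulus_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.stimulus_onsets = np.sort(np.asarray(self.stimulus_onsets, dtype=float))
        if self.time.shape != self.speed.shape:
            raise ValueError("time and speed must match")
        if len(self.stimulus_onsets) == 0:
            raise ValueError("need at least one stimulus onset")


@dataclass(frozen=True)
class EscapeMetrics:
    peak_speed_during: float
    avg_speed_after: float
    avg_speed_before: float


def escape_metrics(
    session: LoomingSession,
    before_s: float = DEFAULT_BEFORE_S,
    during_tail_s: float = DEFAULT_DURING_TAIL_S,
    after_s: float = DEFAULT_AFTER_S,
) -> EscapeMetrics:
    """Peak speed during the stimuli and mean speeds before/after.

    Windows: before = [first onset - before_s, first onset); during =
    [first onset, last onset + during_tail_s]; after = (during end,
    during end + after_s].  All three windows must contain at least one
    speed bin.
    """
    t = session.time
    first, last = session.stimulus_onsets[0], session.stimulus_onsets[-1]
    during_end = last + during_tail_s
    before = (t >= first - before_s) & (t < first)
    during = (t >= first) & (t <= during_end)
    after = (t > during_end) & (t <= during_end + after_s)
    for name, m in (("before", before), ("during", during), ("after", after)):
        if not m.any():
            raise ValueError(f"{name} window contains no speed bins")
    return EscapeMetrics(
        peak_speed_during=float(np.nanmax(session.speed[during])),
        avg_speed_after=float(np.nanmean(session.speed[after])),
        avg_speed_before=float(np.nanmean(session.speed[before])),
    )
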