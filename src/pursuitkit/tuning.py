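"""Single-unit analyses: antidromic identification, peri-event PSTHs,
and locomotion speed tuning.

Putative projection neurons are identified *antidromically*: brief
light pulses over the axon terminals evoke backward-propagating spikes,
and a unit is accepted when its pulse-evoked spikes follow the pulses
reliably at short latency (median < 5 ms) with a waveform matching its
locomotion-evoked spikes (Pearson r of the mean waveforms).

Speed tuning follows the standard treadmill analysis: the recording is
partitioned into 500-ms windows during locomotion, each contributing a
(mean speed, firing rate) pair; rates are binned by speed over the
3-30 cm/s analysis range, normalized per unit to [0, 1], and the
monotonicity of the curve is scored by Spearman rank correlation (exact
permutation p-value for small bin counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .alignment import AlignedResponse

__all__ = [
    "SpikeTrain",
    "LightPulseLog",
    "AntidromicResult",
    "SpeedTuningCurve",
    "identify_antidromic",
    "align_to_events",
    "speed_tuning",
    "speed_tuning_permutation_p",
    "locomotion_bouts",
    "spearman",
]

#: antidromic latency criterion (s): median first-spike latency < 5 ms
ANTIDROMIC_LATENCY_MAX_S = 0.005
#: window searched for a pulse-locked spike (s)
ANTIDROMIC_SEARCH_WINDOW_S = 0.010
#: minimum fraction of pulses followed by a spike
DEFAULT_RELIABILITY_MIN = 0.5
#: minimum Pearson r between pulse-evoked and locomotion waveforms
DEFAULT_SIMILARITY_MIN = 0.9

#: speed-tuning window duration (s) and analysis range (cm/s)
TUNING_WINDOW_S = 0.5
TUNING_SPEED_RANGE = (3.0, 30.0)

#: locomotion-bout hysteresis thresholds (cm/s) and minimum duration (s)
BOUT_ON_CM_S = 3.0
BOUT_OFF_CM_S = 1.0
BOUT_MIN_DURATION_S = 1.0

#: largest sample size for which the Spearman p-value is computed by
#: exhaustive permutation enumeration
EXACT_PERMUTATION_N_MAX = 8


@dataclass
class SpikeTrain:
    """Sorted spike times with optional per-spike waveforms."""

    spike_times: np.ndarray
    waveforms: np.ndarray | None = None
    unit_id: str | int | None = None
    t_start: float = 0.0
    t_stop: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike times must be sorted")
        if self.waveforms is not None:
            self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=float))
            if self.waveforms.shape[0] != len(self.spike_times):
                raise ValueError("one waveform per spike required")
        if self.t_stop is None:
            self.t_stop = float(self.spike_times[-1]) if len(self.spike_times) else 0.0


@dataclass
class LightPulseLog:
    pulse_times: np.ndarray
    pulse_width: float = 0.001
    wavelength_nm: float = 473.0

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if np.any(np.diff(self.pulse_times) < 0):
            raise ValueError("pulse times must be sorted")
        if self.pulse_width <= 0:
            raise ValueError("pulse width must be positive")


@dataclass(frozen=True)
class AntidromicResult:
    median_latency: float | None
    response_reliability: float
    waveform_similarity: float | None
    identified: bool


@dataclass
class SpeedTuningCurve:
    speed_bin_centers: np.ndarray
    normalized_rate: np.ndarray
    bin_mean_rate: np.ndarray
    bin_counts: np.ndarray
    spearman_rho: float | None
    spearman_p: float | None
    bin_duration: float = TUNING_WINDOW_S
    analysis_range: tuple[float, float] = TUNING_SPEED_RANGE
    window_speed: np.ndarray | None = None
    window_rate: np.ndarray | None = None


def _mean_waveform(waveforms: np.ndarray, idx: np.ndarray) -> np.ndarray | None:
    if waveforms is None or len(idx) == 0:
        return None
    return waveforms[idx].mean(axis=0)


def identify_antidromic(
    train: SpikeTrain,
    pulses: LightPulseLog,
    locomotion_spikes: SpikeTrain,
    search_window: float = ANTIDROMIC_SEARCH_WINDOW_S,
    latency_max: float = ANTIDROMIC_LATENCY_MAX_S,
    reliability_min: float = DEFAULT_RELIABILITY_MIN,
    similarity_min: float = DEFAULT_SIMILARITY_MIN,
) -> AntidromicResult:
    """Test whether a unit is antidromically activated by the light pulses.

    For each pulse the first spike within ``search_window`` gives a
    latency; the unit is identified iff the median latency is below
    ``latency_max``, the fraction of pulses followed by a spike is at
    least ``reliability_min``, and the Pearson correlation between the
    mean pulse-evoked and mean locomotion waveforms is at least
    ``similarity_min``.
    """
    if len(pulses.pulse_times) < 20:
        raise ValueError("need >= 20 light pulses")
    if len(locomotion_spikes.spike_times) < 20:
        raise ValueError("need >= 20 locomotion spikes for the template")
    latencies = []
    evoked_idx = []
    for p in pulses.pulse_times:
        j = np.searchsorted(train.spike_times, p, side="right")
        if j < len(train.spike_times) and train.spike_times[j] - p <= search_window:
            latencies.append(train.spike_times[j] - p)
            evoked_idx.append(j)
    reliability = len(latencies) / len(pulses.pulse_times)
    if not latencies:
        return AntidromicResult(None, 0.0, None, False)
    median_latency = float(np.median(latencies))
    similarity = None
    if train.waveforms is not None and locomotion_spikes.waveforms is not None:
        evoked = _mean_waveform(train.waveforms, np.asarray(evoked_idx))
        loco = locomotion_spikes.waveforms.mean(axis=0)
        if evoked is not None and np.std(evoked) > 0 and np.std(loco) > 0:
            similarity = float(np.corrcoef(evoked, loco)[0, 1])
    identified = (
        median_latency < latency_max
        and reliability >= reliability_min
        and similarity is not None
        and similarity >= similarity_min
    )
    return AntidromicResult(median_latency, reliability, similarity, identified)


def align_to_events(
    train: SpikeTrain,
    events: np.ndarray,
    window: tuple[float, float] = (-2.0, 2.0),
    bin_s: float = 0.02,
    baseline_window: tuple[float, float] = (-2.0, -1.0),
) -> AlignedResponse:
    """Peri-event firing-rate matrix, trial average, and Z-score.

    Events whose window extends past the recording span are dropped;
    at least one event must survive.  Rates are per-event binned counts
    divided by the bin width.
    """
    events = np.asarray(events, dtype=float)
    w0, w1 = window
    ok = (events + w0 >= train.t_start) & (events + w1 <= train.t_stop)
    events = events[ok]
    if len(events) == 0:
        raise ValueError("no event lies fully inside the recording")
    edges = np.arange(w0, w1 + bin_s / 2, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    mat = np.empty((len(events), len(centers)))
    for i, ev in enumerate(events):
        counts, _ = np.histogram(train.spike_times - ev, bins=edges)
        mat[i] = counts / bin_s
    return AlignedResponse(
        time=centers, per_trial=mat, baseline_window=baseline_window, kind="rate"
    )


def locomotion_bouts(
    time: np.ndarray,
    speed: np.ndarray,
    on_threshold: float = BOUT_ON_CM_S,
    off_threshold: float = BOUT_OFF_CM_S,
    min_duration: float = BOUT_MIN_DURATION_S,
) -> list[tuple[float, float]]:
    """Locomotion bout (onset, offset) intervals by hysteresis threshold.

    A bout starts when speed reaches ``on_threshold`` and ends when it
    falls below ``off_threshold``; bouts shorter than ``min_duration``
    are discarded.
    """
    time = np.asarray(time, float)
    speed = np.asarray(speed, float)
    bouts = []
    in_bout = False
    onset = 0.0
    for t, v in zip(time, speed):
        if not in_bout and v >= on_threshold:
            in_bout, onset = True, t
        elif in_bout and (v < off_threshold or not np.isfinite(v)):
            if t - onset >= min_duration:
                bouts.append((onset, t))
            in_bout = False
    if in_bout and time[-1] - onset >= min_duration:
        bouts.append((onset, float(time[-1])))
    return bouts


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value is two-sided: exact (full permutation enumeration of the
    rank vector) for n <= 8, the usual t approximation otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_corr(rx, ry)
    if np.isnan(rho):
        return float("nan"), float("nan")
    if n <= EXACT_PERMUTATION_N_MAX:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(ry):
            r = _rank_corr(rx, np.asarray(perm))
            count += abs(r) >= target
            total += 1
        p = count / total
    else:
        # t approximation on n-2 dof
        t = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
        p = min(1.0, p)
    return float(rho), float(p)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = np.sqrt((sx**2).sum() * (sy**2).sum())
    if denom == 0:
        return float("nan")
    return float((sx * sy).sum() / denom)


def speed_tuning(
    train: SpikeTrain,
    time: np.ndarray,
    speed: np.ndarray,
    bouts: list[tuple[float, float]] | None = None,
    window_s: float = TUNING_WINDOW_S,
    speed_range: tuple[float, float] = TUNING_SPEED_RANGE,
    n_bins: int = 9,
    mode: str = "bin",
) -> SpeedTuningCurve:
    """Firing rate as a function of locomotion speed in 500-ms windows.

    Locomotion bouts (detected with default thresholds unless given) are
    partitioned into consecutive non-overlapping windows of
    ``window_s``; each window contributes its mean speed and its firing
    rate.  Windows are binned by speed into ``n_bins`` equal bins over
    ``speed_range``; per-bin mean rates are min-max normalized to
    [0, 1].  ``mode='bin'`` correlates bin centers with bin mean rates
    (the default); ``mode='windows'`` correlates the window-level pairs.
    The correlation is undefined (None) with fewer than 3 occupied bins.
    """
    time = np.asarray(time, float)
    speed = np.asarray(speed, float)
    if bouts is None:
        bouts = locomotion_bouts(time, speed)
    win_speed, win_rate = [], []
    for b0, b1 in bouts:
        n_win = int(np.floor((b1 - b0) / window_s))
        for k in range(n_win):
            w0 = b0 + k * window_s
            w1 = w0 + window_s
            in_win = (time >= w0) & (time < w1)
            if not in_win.any():
                continue
            win_speed.append(float(np.nanmean(speed[in_win])))
            n_spk = np.searchsorted(train.spike_times, w1) - np.searchsorted(
                train.spike_times, w0
            )
            win_rate.append(n_spk / window_s)
    win_speed = np.asarray(win_speed)
    win_rate = np.asarray(win_rate)
    lo, hi = speed_range
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    bin_mean = np.full(n_bins, np.nan)
    bin_counts = np.zeros(n_bins, dtype=int)
    in_range = (win_speed >= lo) & (win_speed <= hi)
    idx = np.clip(np.digitize(win_speed[in_range], edges) - 1, 0, n_bins - 1)
    for b in range(n_bins):
        sel = idx == b
        bin_counts[b] = sel.sum()
        if sel.any():
            bin_mean[b] = win_rate[in_range][sel].mean()
    occupied = np.isfinite(bin_mean)
    if occupied.any() and np.nanmax(bin_mean) > np.nanmin(bin_mean):
        normalized = (bin_mean - np.nanmin(bin_mean)) / (
            np.nanmax(bin_mean) - np.nanmin(bin_mean)
        )
    else:
        normalized = np.where(occupied, 0.0, np.nan)
    rho = p = None
    if mode == "bin":
        if occupied.sum() >= 3:
            rho, p = spearman(centers[occupied], bin_mean[occupied])
    elif mode == "windows":
        if in_range.sum() >= 3 and occupied.sum() >= 3:
            rho, p = spearman(win_speed[in_range], win_rate[in_range])
    else:
        raise ValueError("mode must be 'bin' or 'windows'")
    return SpeedTuningCurve(
        speed_bin_centers=centers,
        normalized_rate=normalized,
        bin_mean_rate=bin_mean,
        bin_counts=bin_counts,
        spearman_rho=rho,
        spearman_p=p,
        bin_duration=window_s,
        analysis_range=speed_range,
        window_speed=win_speed,
        window_rate=win_rate,
    )


def speed_tuning_permutation_p(
    curve: SpeedTuningCurve, n_perm: int = 499, seed: int = 0
) -> float:
    """Permutation p-value for the bin-level tuning correlation.

    Bin mean rates have unequal window counts, so permuting bin *ranks*
    is not a valid null (low-occupancy bins are noisier).  The proper
    exchangeable unit is the 500-ms window: this shuffles the pairing
    of window rates to window speeds, recomputes the binned curve and
    its bin-level Spearman rho for each shuffle, and returns the
    two-sided Monte-Carlo p-value with the observed statistic included
    (so the test is exactly valid at any level).
    """
    if curve.window_speed is None or curve.window_rate is None:
        raise ValueError("curve lacks window-level data")
    lo, hi = curve.analysis_range
    n_bins = len(curve.speed_bin_centers)
    ws = np.asarray(curve.window_speed, float)
    wr = np.asarray(curve.window_rate, float)
    in_range = (ws >= lo) & (ws <= hi)
    ws, wr = ws[in_range], wr[in_range]
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(ws, edges) - 1, 0, n_bins - 1)
    occ = np.unique(idx)
    if len(occ) < 3:
        raise ValueError("fewer than 3 occupied speed bins")
    # averaging matrix: occupied bins x windows
    G = np.zeros((len(occ), len(ws)))
    for row, b in enumerate(occ):
        sel = idx == b
        G[row, sel] = 1.0 / sel.sum()
    rc = stats.rankdata(curve.speed_bin_centers[occ])
    obs = abs(_rank_corr(rc, stats.rankdata(G @ wr)))
    rng = np.random.default_rng(seed)
    perms = np.empty((len(wr), n_perm))
    for j in range(n_perm):
        perms[:, j] = rng.permutation(wr)
    bin_means = G @ perms
    ranks = stats.rankdata(bin_means, axis=0)
    rcs = (rc - rc.mean())[:, None]
    rk = ranks - ranks.mean(axis=0, keepdims=True)
    denom = np.sqrt((rcs**2).sum() * (rk**2).sum(axis=0))
    with np.errstate(invalid="ignore"):
        rho_perm = np.abs((rcs * rk).sum(axis=0) / denom)
    rho_perm = rho_perm[np.isfinite(rho_perm)]
    return float((1 + np.sum(rho_perm >= obs - 1e-12)) / (len(rho_perm) + 1))
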