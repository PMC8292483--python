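"""Synthetic speed-tuned spike trains with antidromic light responses.

Spikes are drawn from an inhomogeneous Poisson process whose rate is a
linear function of locomotion speed evaluated a fixed *lead* into the
future (the unit's activity precedes the movement):

    rate(t) = baseline_rate + slope * speed(t + onset_lead)

clipped at zero.  A block of light pulses appended after the behavioral
recording evokes antidromic spikes at a planted latency with Gaussian
jitter; per-spike waveforms are a fixed template plus noise, so the
pulse-evoked and locomotion-evoked mean waveforms correlate highly
unless a deliberately different antidromic template is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..tuning import LightPulseLog, SpikeTrain
from ._rng import spawn_rngs
from .groundtruth import GroundTruth

__all__ = ["TuningParams", "generate_speed_tuned_spikes", "treadmill_speed"]

logger = logging.getLogger(__name__)


def default_waveform_template(n_samples: int = 32) -> np.ndarray:
    """Biphasic extracellular spike shape (arbitrary amplitude units)."""
    t = np.linspace(0, 1, n_samples)
    return -np.exp(-(((t - 0.3) / 0.08) ** 2)) + 0.5 * np.exp(
        -(((t - 0.55) / 0.15) ** 2)
    )


@dataclass
class TuningParams:
    """Parameters of a synthetic speed-tuned unit."""

    baseline_rate: float = 5.0  # Hz at speed 0
    slope: float = 0.8  # Hz per cm/s
    speed_range: tuple[float, float] = (3.0, 30.0)
    onset_lead: float = 0.1  # s the rate leads the speed signal
    antidromic_latency: float = 0.003  # s
    latency_jitter_sd: float = 0.0002  # s
    antidromic_reliability: float = 0.95
    waveform_template: np.ndarray | None = None
    antidromic_template: np.ndarray | None = None  # defaults to same template
    waveform_noise_sd: float = 0.05
    n_pulses: int = 100
    pulse_interval: float = 0.5
    pulse_width: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.onset_lead < 0:
            raise ValueError("onset_lead must be >= 0")
        if self.waveform_template is None:
            self.waveform_template = default_waveform_template()
        self.waveform_template = np.asarray(self.waveform_template, float)
        if self.antidromic_template is None:
            self.antidromic_template = self.waveform_template
        self.antidromic_template = np.asarray(self.antidromic_template, float)


def treadmill_speed(
    duration: float,
    frame_rate: float = 50.0,
    peak_range: tuple[float, float] = (10.0, 30.0),
    bout_duration: tuple[float, float] = (2.0, 4.0),
    rest_duration: tuple[float, float] = (3.0, 5.0),
    rise_time: float = 0.25,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Treadmill-style locomotion speed: rests alternating with bouts.

    Each bout ramps linearly from 0 to a per-bout peak over
    ``rise_time``, holds, and ramps back down.  Returns (time, speed).
    """
    (rng,) = spawn_rngs(seed, 1)
    dt = 1.0 / frame_rate
    n = int(round(duration / dt))
    time = np.arange(n) * dt
    speed = np.zeros(n)
    t = float(rng.uniform(*rest_duration))
    while t < duration:
        peak = rng.uniform(*peak_range)
        dur = rng.uniform(*bout_duration)
        t0, t1 = t, min(t + dur, duration)
        seg = (time >= t0) & (time < t1)
        tt = time[seg]
        ramp_up = np.clip((tt - t0) / rise_time, 0, 1)
        ramp_down = np.clip((t1 - tt) / rise_time, 0, 1)
        speed[seg] = peak * np.minimum(ramp_up, ramp_down)
        t = t1 + float(rng.uniform(*rest_duration))
    return time, speed


def generate_speed_tuned_spikes(
    params: TuningParams,
    time: np.ndarray,
    speed: np.ndarray,
    rate_dt: float = 0.001,
) -> tuple[SpikeTrain, LightPulseLog, GroundTruth]:
    """Draw one unit's spike train given a locomotion speed series.

    The behavioral recording spans the speed series; a light-pulse
    block follows 2 s after it.  Returns the merged spike train (with
    waveforms), the pulse log, and the planted ground truth.
    """
    p = params
    rng_spk, rng_anti, rng_wf = spawn_rngs(p.seed, 3)
    time = np.asarray(time, float)
    speed = np.asarray(speed, float)

    # behavioral spikes: inhomogeneous Poisson on a fine grid
    grid = np.arange(time[0], time[-1], rate_dt)
    lead_speed = np.interp(grid + p.onset_lead, time, speed)
    rate = p.baseline_rate + p.slope * lead_speed
    n_clip = int(np.sum(rate < 0))
    if n_clip:
        logger.info("clipped %d negative-rate samples to 0", n_clip)
        rate = np.clip(rate, 0, None)
    counts = rng_spk.poisson(rate * rate_dt)
    idx = np.repeat(np.arange(len(grid)), counts)
    beh_spikes = np.sort(grid[idx] + rng_spk.uniform(0, rate_dt, size=len(idx)))

    # antidromic block after the behavior
    pulse_start = time[-1] + 2.0
    pulses = pulse_start + p.pulse_interval * np.arange(p.n_pulses)
    responding = rng_anti.random(p.n_pulses) < p.antidromic_reliability
    latencies = p.antidromic_latency + rng_anti.normal(
        0, p.latency_jitter_sd, p.n_pulses
    )
    anti_spikes = np.sort(pulses[responding] + latencies[responding])

    all_times = np.concatenate([beh_spikes, anti_spikes])
    order = np.argsort(all_times, kind="stable")
    all_times = all_times[order]
    templates = np.concatenate(
        [
            np.tile(p.waveform_template, (len(beh_spikes), 1)),
            np.tile(p.antidromic_template, (len(anti_spikes), 1)),
        ]
    )[order]
    waveforms = templates + rng_wf.normal(0, p.waveform_noise_sd, templates.shape)

    train = SpikeTrain(
        spike_times=all_times,
        waveforms=waveforms,
        t_start=float(time[0]),
        t_stop=float(pulses[-1] + 1.0),
    )
    log = LightPulseLog(pulse_times=pulses, pulse_width=p.pulse_width)
    gt = GroundTruth(
        modality="spikes",
        params={
            "speed_range": list(p.speed_range),
            "latency_jitter_sd": p.latency_jitter_sd,
            "antidromic_reliability": p.antidromic_reliability,
            "n_pulses": p.n_pulses,
            "seed": p.seed,
        },
        baseline_rate=p.baseline_rate,
        slope=p.slope,
        onset_lead=p.onset_lead,
        antidromic_latency=p.antidromic_latency,
    )
    return train, log, gt
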