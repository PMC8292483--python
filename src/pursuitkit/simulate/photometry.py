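"""Synthetic fiber-photometry traces with planted transients.

Locomotion-coupled mode: each locomotion onset plants one transient
whose rise begins ``transient_lead`` seconds *before* the onset,
emulating dopamine release preceding movement initiation.  Evoked mode:
single light pulses of varying laser power plant transients whose
amplitude follows a monotone saturating input-output map, scaled by a
``suppression_factor`` in [0, 1] that emulates pharmacological receptor
blockade (1 = untreated, 0 = full blockade).

The transient kernel is a dual exponential (fast rise, slow decay)
normalized to unit peak; the raw trace is F0 * (1 + dff) plus Gaussian
noise, so the planted dF/F amplitudes are recovered by the analysis
pipeline's percentile-baseline dF/F.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from ..photometry import FluorescenceTrace
from ._rng import spawn_rngs
from .groundtruth import GroundTruth

__all__ = [
    "PhotometryParams",
    "saturating_power_map",
    "generate_photometry",
    "generate_evoked_session",
]


def saturating_power_map(max_amplitude: float = 0.1, half_power_mw: float = 5.0):
    """Monotone saturating laser-power -> dF/F amplitude map (0 mW -> 0)."""

    def f(power_mw: float) -> float:
        return max_amplitude * power_mw / (power_mw + half_power_mw)

    return f


@dataclass
class PhotometryParams:
    """Parameters of a synthetic photometry session."""

    sample_rate: float = 100.0  # Hz
    kernel_decay: float = 0.5  # s
    kernel_rise: float = 0.02  # s
    transient_lead: float = 0.125  # s before locomotion onset
    transient_amplitude: float = 0.05  # dF/F
    noise_sd: float = 0.005  # dF/F units
    f0: float = 100.0  # baseline fluorescence, arbitrary units
    evoked_amplitude_vs_power: Callable[[float], float] = field(
        default_factory=saturating_power_map
    )
    suppression_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not 0.0 <= self.suppression_factor <= 1.0:
            raise ValueError("suppression_factor must lie in [0, 1]")
        if abs(self.evoked_amplitude_vs_power(0.0)) > 1e-12:
            raise ValueError("evoked amplitude at 0 mW must be 0")


def _kernel(p: PhotometryParams, t: np.ndarray) -> np.ndarray:
    """Unit-peak dual-exponential transient kernel evaluated at t >= 0."""
    k = np.where(
        t >= 0, (1 - np.exp(-np.maximum(t, 0) / p.kernel_rise)) * np.exp(-np.maximum(t, 0) / p.kernel_decay), 0.0
    )
    # normalize to unit peak (peak at kernel_rise * log(1 + decay/rise))
    tp = p.kernel_rise * np.log(1 + p.kernel_decay / p.kernel_rise)
    peak = (1 - np.exp(-tp / p.kernel_rise)) * np.exp(-tp / p.kernel_decay)
    return k / peak


def _plant_transients(
    p: PhotometryParams,
    duration: float,
    start_times: np.ndarray,
    amplitudes: np.ndarray,
    rng,
    channel: str,
) -> FluorescenceTrace:
    dt = 1.0 / p.sample_rate
    time = np.arange(int(round(duration / dt))) * dt
    dff = np.zeros_like(time)
    span = 6 * p.kernel_decay
    for t0, a in zip(start_times, amplitudes):
        seg = (time >= t0) & (time <= t0 + span)
        dff[seg] += a * _kernel(p, time[seg] - t0)
    raw = p.f0 * (1.0 + dff)
    if p.noise_sd > 0:
        raw = raw + p.f0 * p.noise_sd * rng.standard_normal(len(time))
    return FluorescenceTrace(time=time, raw=raw, channel=channel)


def generate_photometry(
    params: PhotometryParams,
    locomotion_onsets: np.ndarray,
    duration: float,
) -> tuple[FluorescenceTrace, GroundTruth]:
    """Trace with one transient planted before each locomotion onset."""
    p = params
    (rng,) = spawn_rngs(p.seed, 1)
    onsets = np.asarray(locomotion_onsets, float)
    if len(onsets) and (onsets.min() < 0 or onsets.max() > duration):
        raise ValueError("locomotion onsets must lie within the trace span")
    starts = onsets - p.transient_lead
    amps = np.full(len(starts), p.transient_amplitude)
    trace = _plant_transients(p, duration, starts, amps, rng, "sensor")
    gt = GroundTruth(
        modality="photometry",
        params={
            "sample_rate": p.sample_rate,
            "kernel_decay": p.kernel_decay,
            "kernel_rise": p.kernel_rise,
            "noise_sd": p.noise_sd,
            "transient_amplitude": p.transient_amplitude,
            "seed": p.seed,
        },
        transient_lead=p.transient_lead,
    )
    return trace, gt


def generate_evoked_session(
    params: PhotometryParams,
    powers_mw: np.ndarray,
    n_pulses_per_power: int = 20,
    pulse_interval: float = 4.0,
    channel: str = "sensor",
) -> tuple[FluorescenceTrace, pd.DataFrame, GroundTruth]:
    """Trace with light-evoked transients at each laser power.

    Pulses of each power are delivered in interleaved order at a fixed
    interval (default 4 s, at least eight kernel decay constants, so
    consecutive evoked transients never overlap); each plants a
    transient of amplitude
    ``evoked_amplitude_vs_power(power) * suppression_factor``.  A
    'control' channel plants zero-amplitude transients (sensor absent).
    Returns the trace, a pulse table (time, power_mw), and the ground
    truth with the planted per-power amplitudes.
    """
    p = params
    (rng,) = spawn_rngs(p.seed, 1)
    powers_mw = np.asarray(powers_mw, float)
    order = np.tile(powers_mw, n_pulses_per_power)
    times = 5.0 + pulse_interval * np.arange(len(order))
    duration = times[-1] + 5.0
    planted = {
        float(pw): float(p.evoked_amplitude_vs_power(pw) * p.suppression_factor)
        for pw in powers_mw
    }
    amps = np.array([planted[float(pw)] for pw in order])
    if channel == "control":
        amps = np.zeros_like(amps)
    trace = _plant_transients(p, duration, times, amps, rng, channel)
    pulse_table = pd.DataFrame({"time": times, "power_mw": order})
    gt = GroundTruth(
        modality="photometry_evoked",
        params={
            "n_pulses_per_power": n_pulses_per_power,
            "pulse_interval": pulse_interval,
            "noise_sd": p.noise_sd,
            "channel": channel,
            "seed": p.seed,
        },
        suppression_factor=p.suppression_factor,
        evoked_amplitudes=planted,
    )
    return trace, pulse_table, gt
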