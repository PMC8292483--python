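"""Synthetic looming-escape sessions.

The animal explores at a constant baseline speed (smoothly turning,
reflected off the walls), three cycles of an overhead expanding-disk
stimulus are presented, and after a short latency the animal dashes at
the planted escape speed before freezing for the rest of the session.
Because binned speed is path length per bin, baseline and escape bins
recover the planted speeds exactly at zero noise regardless of turning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..kinematics import Trajectory, compute_speed
from ..locomotor import LoomingSession
from ._rng import spawn_rngs
from .groundtruth import GroundTruth

__all__ = ["LoomingParams", "StimulusLog", "generate_looming_trial", "session_from_trial"]


@dataclass
class StimulusLog:
    """Overhead looming stimuli: onsets plus the fixed stimulus metadata
    (disk expands 2 deg -> 20 deg in 250 ms; background/disk luminances
    3.6 / 0.1 cd/m^2)."""

    onsets: np.ndarray
    expansion_deg: tuple[float, float] = (2.0, 20.0)
    expansion_s: float = 0.25
    luminance_cdm2: tuple[float, float] = (3.6, 0.1)

    def __post_init__(self) -> None:
        self.onsets = np.sort(np.asarray(self.onsets, float))


@dataclass
class LoomingParams:
    baseline_speed: float = 8.0  # cm/s exploration
    escape_speed: float = 40.0  # cm/s dash
    n_cycles: int = 3
    stimulus_interval: float = 1.0  # s between cycle onsets
    first_stimulus: float = 12.0  # s
    escape_latency: float = 0.1  # s after first onset
    escape_duration: float = 0.8  # s
    freeze_duration: float = 12.0  # s after the dash
    frame_rate: float = 50.0
    arena_size: tuple[float, float] = (35.0, 35.0)
    position_noise_sd: float = 0.0
    seed: int = 0


def generate_looming_trial(
    params: LoomingParams,
) -> tuple[Trajectory, StimulusLog, GroundTruth]:
    p = params
    rng_path, rng_noise = spawn_rngs(p.seed, 2)
    dt = 1.0 / p.frame_rate
    onsets = p.first_stimulus + p.stimulus_interval * np.arange(p.n_cycles)
    escape_start = onsets[0] + p.escape_latency
    escape_end = escape_start + p.escape_duration
    duration = escape_end + p.freeze_duration
    n = int(round(duration / dt))
    time = np.arange(n) * dt

    lo, hi = 3.0, min(p.arena_size) - 3.0
    pos = np.array(p.arena_size) / 2.0
    ang = rng_path.uniform(0, 2 * np.pi)
    xy = np.empty((n, 2))
    heading = np.empty((n, 2))
    corner = np.array([lo, lo])
    for i, t in enumerate(time):
        if t < escape_start:
            speed = p.baseline_speed
            ang += rng_path.normal(0, 0.15)
        elif t < escape_end:
            speed = p.escape_speed
            ang = float(np.arctan2(corner[1] - pos[1], corner[0] - pos[0]))
        else:
            speed = 0.0
        step = speed * dt * np.array([np.cos(ang), np.sin(ang)])
        nxt = pos + step
        if not (lo <= nxt[0] <= hi and lo <= nxt[1] <= hi):
            ang += np.pi
            nxt = pos + speed * dt * np.array([np.cos(ang), np.sin(ang)])
            nxt = np.clip(nxt, lo, hi)
        xy[i] = pos
        heading[i] = [np.cos(ang), np.sin(ang)]
        pos = nxt
    head = xy + 2.0 * heading
    if p.position_noise_sd > 0:
        xy = xy + rng_noise.normal(0, p.position_noise_sd, xy.shape)
        head = head + rng_noise.normal(0, p.position_noise_sd, head.shape)
    traj = Trajectory(time=time, predator=xy, head=head, arena_size=p.arena_size)
    stim = StimulusLog(onsets=onsets)
    gt = GroundTruth(
        modality="looming",
        params={
            "escape_latency": p.escape_latency,
            "escape_duration": p.escape_duration,
            "frame_rate": p.frame_rate,
            "position_noise_sd": p.position_noise_sd,
            "seed": p.seed,
        },
        baseline_speed=p.baseline_speed,
        escape_speed=p.escape_speed,
        stimulus_onsets=[float(t) for t in onsets],
    )
    return traj, stim, gt


def session_from_trial(
    traj: Trajectory, stim: StimulusLog, bin_s: float = 0.2
) -> LoomingSession:
    """Bin the trajectory into a 200-ms speed series around the stimuli."""
    bin_time, speed = compute_speed(traj, bin_s=bin_s)
    return LoomingSession(
        time=bin_time,
        speed=speed,
        stimulus_onsets=stim.onsets,
        stimulus_meta={
            "expansion_deg": stim.expansion_deg,
            "expansion_s": stim.expansion_s,
            "luminance_cdm2": stim.luminance_cdm2,
        },
    )
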