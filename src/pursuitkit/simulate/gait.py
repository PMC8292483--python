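"""Synthetic runway gait: four paws alternating stance and swing.

The body advances at constant speed; each paw cycles at the planted
step frequency with a duty cycle split between stance (paw planted on
the ground while the body advances) and swing (paw carried forward by
one stride).  The planted stride length is body_speed / step_frequency
by construction.  Diagonal paw pairs move in antiphase (trot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..locomotor import PawTraces
from ._rng import spawn_rngs
from .groundtruth import GroundTruth

__all__ = ["GaitParams", "generate_gait"]

#: trot phase offsets per paw (fraction of a cycle)
_PHASES = {"LF": 0.0, "RH": 0.0, "RF": 0.5, "LH": 0.5}
#: resting paw offsets relative to the body centroid (cm): (along, lateral)
_OFFSETS = {"LF": (3.0, 1.0), "RF": (3.0, -1.0), "LH": (-3.0, 1.0), "RH": (-3.0, -1.0)}


@dataclass
class GaitParams:
    body_speed: float = 20.0  # cm/s
    step_frequency: float = 4.0  # Hz
    duty_cycle: float = 0.6  # stance fraction of the cycle
    paw_noise_sd: float = 0.0  # cm
    frame_rate: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_cycle < 1.0:
            raise ValueError("duty_cycle must lie in (0, 1)")
        if self.body_speed <= 0 or self.step_frequency <= 0:
            raise ValueError("body_speed and step_frequency must be positive")

    @property
    def stride_length(self) -> float:
        return self.body_speed / self.step_frequency


def _paw_progress(phase: np.ndarray, duty: float) -> np.ndarray:
    """Strides completed at cycle phase (cycles + fractional swing)."""
    whole = np.floor(phase)
    frac = phase - whole
    swing = np.clip((frac - duty) / (1.0 - duty), 0.0, 1.0)
    return whole + swing


def generate_gait(
    params: GaitParams, duration: float
) -> tuple[PawTraces, GroundTruth]:
    """Paw and body traces for ``duration`` seconds of steady walking."""
    p = params
    (rng,) = spawn_rngs(p.seed, 1)
    dt = 1.0 / p.frame_rate
    n = int(round(duration / dt))
    time = np.arange(n) * dt
    body = np.column_stack([5.0 + p.body_speed * time, np.zeros(n)])
    stride = p.stride_length
    paws = {}
    for label in _PHASES:
        phase = p.step_frequency * time + _PHASES[label]
        x = 5.0 + _OFFSETS[label][0] + stride * _paw_progress(phase, p.duty_cycle)
        y = np.full(n, _OFFSETS[label][1])
        xy = np.column_stack([x, y])
        if p.paw_noise_sd > 0:
            xy = xy + rng.normal(0, p.paw_noise_sd, xy.shape)
        paws[label] = xy
    traces = PawTraces(time=time, paws=paws, body=body)
    gt = GroundTruth(
        modality="gait",
        params={
            "body_speed": p.body_speed,
            "duty_cycle": p.duty_cycle,
            "paw_noise_sd": p.paw_noise_sd,
            "frame_rate": p.frame_rate,
            "duration": duration,
            "seed": p.seed,
        },
        step_frequency=p.step_frequency,
        stride_length=stride,
    )
    return traces, gt
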