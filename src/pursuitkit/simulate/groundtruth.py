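"""Ground-truth records for synthetic datasets.

Every generator returns a :class:`GroundTruth` alongside its data: the
planted quantities (episode intervals, peak speeds, attack times,
tuning slope, onset lead, gait parameters, puncta count, ...) plus an
echo of the generator parameters.  Records serialize to JSON and
round-trip identically, so recovery tests can be anchored to files as
well as in-memory objects.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class GroundTruth:
    """Planted quantities of one synthetic dataset.

    Only the fields relevant to the generating modality are set; the
    rest stay None.  ``params`` echoes the generator parameters.
    """

    modality: str = ""
    params: dict = field(default_factory=dict)
    # hunting
    episode_intervals: list | None = None  # [(start_s, end_s), ...]
    episode_peak_speeds: list | None = None  # cm/s per episode
    attack_times: list | None = None
    capture_time: float | None = None
    # spikes / photometry
    onset_lead: float | None = None  # s, signal leads event by this much
    baseline_rate: float | None = None
    slope: float | None = None
    antidromic_latency: float | None = None
    transient_lead: float | None = None
    suppression_factor: float | None = None
    evoked_amplitudes: dict | None = None  # power (mW) -> planted amplitude
    # gait
    step_frequency: float | None = None
    stride_length: float | None = None
    # looming
    baseline_speed: float | None = None
    escape_speed: float | None = None
    stimulus_onsets: list | None = None
    # puncta
    puncta_count: int | None = None
    region_area_px: int | None = None

    def to_dict(self) -> dict:
        return _jsonable(dataclasses.asdict(self))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        gt = cls(**data)
        # JSON turns tuples into lists; normalize for round-trip equality
        return gt

    def __eq__(self, other) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return self.to_dict() == other.to_dict()
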