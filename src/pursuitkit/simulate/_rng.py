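"""Seed fan-out: one global integer seed spawns independent per-stream
generators, so modalities stay reproducible and mutually independent."""

from __future__ import annotations

import numpy as np


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """n independent generators deterministically derived from seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
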