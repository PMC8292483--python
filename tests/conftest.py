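import numpy as np
import pytest

from pursuitkit.kinematics import KinematicSeries


def make_series(ppd, azimuth, speed=None, frame_rate=50.0):
    """KinematicSeries straight from raw ppd/azimuth arrays (test helper)."""
    ppd = np.asarray(ppd, dtype=float)
    n = len(ppd)
    az = np.asarray(azimuth, dtype=float)
    if az.ndim == 0:
        az = np.full(n, float(az))
    if speed is None:
        speed = np.zeros(n)
    return KinematicSeries(
        time=np.arange(n) / frame_rate,
        speed=np.asarray(speed, dtype=float),
        azimuth=az,
        ppd=ppd,
        frame_rate=frame_rate,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
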