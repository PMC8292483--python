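"""Kinematic series derived from predator-prey tracking tables.

All downstream hunting analyses consume three derived series computed
here from a :class:`Trajectory`:

* instantaneous locomotion **speed** of the predator, computed as path
  length per fixed time bin (200 ms by default),
* the signed **azimuth** angle between the predator's head direction and
  the bearing to the prey (0 deg = prey dead ahead, positive = prey to
  the animal's left),
* the **predator-prey distance** (PPD), the Euclidean distance between
  the predator centroid and the prey.

Tracking tables are expected at a uniform frame rate (50 frames/s in the
assays this package models).  Missing frames (NaN coordinates) are
linearly interpolated up to a configurable gap limit; longer gaps
propagate as missing values rather than zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "KinematicSeries",
    "compute_speed",
    "compute_azimuth",
    "compute_ppd",
    "kinematic_series",
    "read_tracking_csv",
    "write_tracking_csv",
]

#: maximum run of missing frames bridged by linear interpolation
DEFAULT_GAP_LIMIT = 3

#: speed bin duration in seconds (200 ms)
DEFAULT_SPEED_BIN_S = 0.2


@dataclass
class Trajectory:
    """Synchronized predator/prey positions at a fixed frame rate.

    Parameters
    ----------
    time:
        Strictly increasing, uniformly spaced timestamps in seconds.
    predator:
        ``(n, 2)`` predator body-centroid positions in cm.
    head:
        ``(n, 2)`` predator head-point positions in cm.  The head
        direction is the centroid->head vector.
    prey:
        Optional ``(n, 2)`` prey centroid positions in cm.
    arena_size:
        Optional ``(width, height)`` of the arena in cm.
    """

    time: np.ndarray
    predator: np.ndarray
    head: np.ndarray | None = None
    prey: np.ndarray | None = None
    arena_size: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.predator = np.asarray(self.predator, dtype=float)
        if self.head is not None:
            self.head = np.asarray(self.head, dtype=float)
        if self.prey is not None:
            self.prey = np.asarray(self.prey, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise ValueError("time must be a 1-D array with >= 2 frames")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("timestamps must be uniformly spaced")
        for name in ("predator", "head", "prey"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != (len(self.time), 2):
                raise ValueError(f"{name} must have shape (n_frames, 2)")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


@dataclass
class KinematicSeries:
    """Derived per-frame series consumed by the analysis modules.

    ``speed`` is piecewise constant on the binning grid (each frame
    carries its bin's value); ``speed_bin_time``/``speed_bins`` expose
    the underlying binned series (bin start times and values).
    """

    time: np.ndarray
    speed: np.ndarray
    azimuth: np.ndarray | None
    ppd: np.ndarray | None
    speed_bin_time: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    speed_bins: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    frame_rate: float = 50.0

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("speed", "azimuth", "ppd"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} must match the time base length")


def _interpolate_gaps(x: np.ndarray, gap_limit: int) -> np.ndarray:
    """Linearly bridge NaN runs of length <= gap_limit; longer runs stay NaN."""
    x = np.array(x, dtype=float)
    isnan = np.isnan(x)
    if not isnan.any():
        return x
    n = len(x)
    idx = np.arange(n)
    # identify NaN runs
    run_start = None
    for i in range(n + 1):
        if i < n and isnan[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            run_len = i - run_start
            if run_len <= gap_limit and run_start > 0 and i < n:
                x[run_start:i] = np.interp(
                    idx[run_start:i], [run_start - 1, i], [x[run_start - 1], x[i]]
                )
            run_start = None
    return x


def _clean_xy(xy: np.ndarray, gap_limit: int) -> np.ndarray:
    out = np.column_stack(
        [_interpolate_gaps(xy[:, 0], gap_limit), _interpolate_gaps(xy[:, 1], gap_limit)]
    )
    # a frame missing either coordinate is missing entirely
    bad = np.isnan(out).any(axis=1)
    out[bad] = np.nan
    return out


def compute_speed(
    traj: Trajectory,
    bin_s: float = DEFAULT_SPEED_BIN_S,
    gap_limit: int = DEFAULT_GAP_LIMIT,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned locomotion speed of the predator centroid.

    The speed in each bin is the path length traveled within the bin
    divided by the bin duration.  The step from the last frame of a bin
    to the first frame of the next bin is attributed to the earlier bin,
    so uniform motion at ``v`` yields exactly ``v`` in every complete
    bin.  A trailing partial bin is dropped.

    Returns
    -------
    (bin_start_times, speed):
        arrays of equal length; ``speed`` is cm/s, NaN where the bin
        contains unbridged missing frames.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    frames_per_bin = bin_s * traj.frame_rate
    if frames_per_bin < 2:
        raise ValueError("need >= 2 frames per speed bin")
    xy = _clean_xy(traj.predator, gap_limit)
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)  # step i: frame i -> i+1
    t0 = traj.time[0]
    bin_of_step = np.floor((traj.time[:-1] - t0) / bin_s + 1e-9).astype(int)
    n_bins = int(np.floor((traj.time[-1] - t0) / bin_s + 1e-9))
    if n_bins < 1:
        raise ValueError("trajectory shorter than one speed bin")
    path = np.zeros(n_bins)
    nan_in_bin = np.zeros(n_bins, dtype=bool)
    valid = bin_of_step < n_bins
    np.add.at(path, bin_of_step[valid], np.nan_to_num(steps[valid]))
    nan_steps = np.isnan(steps) & valid
    if nan_steps.any():
        np.logical_or.at(nan_in_bin, bin_of_step[nan_steps], True)
    speed = path / bin_s
    speed[nan_in_bin] = np.nan
    bin_time = t0 + bin_s * np.arange(n_bins)
    return bin_time, speed


def compute_azimuth(traj: Trajectory) -> np.ndarray:
    """Signed head-to-prey azimuth angle per frame, in degrees.

    The angle is measured from the head-direction vector (centroid ->
    head point) to the centroid -> prey vector.  0 deg means the prey is
    dead ahead; positive angles place the prey to the animal's left
    (counter-clockwise in the standard x-y frame).  The anti-collinear
    case is reported as +180 deg.  Frames where the head point coincides
    with the centroid, or where any position is missing, are NaN.
    """
    if traj.head is None or traj.prey is None:
        raise ValueError("azimuth requires head and prey positions")
    h = traj.head - traj.predator
    r = traj.prey - traj.predator
    cross = h[:, 0] * r[:, 1] - h[:, 1] * r[:, 0]
    dot = h[:, 0] * r[:, 0] + h[:, 1] * r[:, 1]
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(cross, dot))
    degenerate = (np.linalg.norm(h, axis=1) == 0) | (np.linalg.norm(r, axis=1) == 0)
    ang[degenerate] = np.nan
    # deterministic tie-break: exactly anti-collinear reported as +180
    ang[ang == -180.0] = 180.0
    return ang


def compute_ppd(traj: Trajectory) -> np.ndarray:
    """Predator-prey distance per frame (cm): centroid-to-prey Euclidean."""
    if traj.prey is None:
        raise ValueError("PPD requires prey positions")
    return np.linalg.norm(traj.prey - traj.predator, axis=1)


def kinematic_series(
    traj: Trajectory,
    speed_bin_s: float = DEFAULT_SPEED_BIN_S,
    gap_limit: int = DEFAULT_GAP_LIMIT,
) -> KinematicSeries:
    """Bundle speed, azimuth, and PPD on the trajectory's frame grid.

    Speed is computed on the binning grid and broadcast per frame
    (frames in a dropped trailing partial bin carry NaN).
    """
    bin_time, speed_bins = compute_speed(traj, speed_bin_s, gap_limit)
    bin_idx = np.floor((traj.time - traj.time[0]) / speed_bin_s + 1e-9).astype(int)
    speed = np.full(traj.n_frames, np.nan)
    inside = bin_idx < len(speed_bins)
    speed[inside] = speed_bins[bin_idx[inside]]
    azimuth = None
    ppd = None
    if traj.prey is not None:
        ppd = compute_ppd(traj)
        if traj.head is not None:
            azimuth = compute_azimuth(traj)
    return KinematicSeries(
        time=traj.time.copy(),
        speed=speed,
        azimuth=azimuth,
        ppd=ppd,
        speed_bin_time=bin_time,
        speed_bins=speed_bins,
        frame_rate=traj.frame_rate,
    )


_COLUMNS = ["time", "pred_x", "pred_y", "head_x", "head_y", "prey_x", "prey_y"]


def read_tracking_csv(path) -> Trajectory:
    """Read a tracking table (columns: time, pred_x/y, head_x/y, prey_x/y)."""
    df = pd.read_csv(path)
    missing = [c for c in ("time", "pred_x", "pred_y") if c not in df.columns]
    if missing:
        raise ValueError(f"tracking CSV missing columns: {missing}")
    head = prey = None
    if {"head_x", "head_y"} <= set(df.columns):
        head = df[["head_x", "head_y"]].to_numpy()
    if {"prey_x", "prey_y"} <= set(df.columns):
        prey = df[["prey_x", "prey_y"]].to_numpy()
    return Trajectory(
        time=df["time"].to_numpy(),
        predator=df[["pred_x", "pred_y"]].to_numpy(),
        head=head,
        prey=prey,
    )


def write_tracking_csv(traj: Trajectory, path) -> None:
    data = {"time": traj.time, "pred_x": traj.predator[:, 0], "pred_y": traj.predator[:, 1]}
    if traj.head is not None:
        data["head_x"], data["head_y"] = traj.head[:, 0], traj.head[:, 1]
    if traj.prey is not None:
        data["prey_x"], data["prey_y"] = traj.prey[:, 0], traj.prey[:, 1]
    pd.DataFrame(data).to_csv(path, index=False)
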