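"""On-disk interchange helpers.

Tracking tables, event logs, and paw tables travel as CSV; micrographs
and region masks as single-channel TIFF; ground truth and parameters as
JSON (see :meth:`pursuitkit.simulate.GroundTruth.to_json`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .kinematics import read_tracking_csv, write_tracking_csv  # re-export

__all__ = [
    "read_tracking_csv",
    "write_tracking_csv",
    "read_events_csv",
    "write_events_csv",
    "read_image_tiff",
    "write_image_tiff",
]


def write_events_csv(times: np.ndarray, path, column: str = "time") -> None:
    pd.DataFrame({column: np.asarray(times, float)}).to_csv(path, index=False)


def read_events_csv(path, column: str = "time") -> np.ndarray:
    return pd.read_csv(path)[column].to_numpy(dtype=float)


def write_image_tiff(image: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(image))


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(path)
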