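"""Synthetic punctate fluorescence micrographs.

Bright non-overlapping disks (puncta) are placed uniformly inside a
region mask on a noisy background; the planted count and centers are
recorded.  Disks are separated by at least one disk diameter plus a
guard band so connected-component counting on the noise-free image
recovers the count exactly.
"""

from __future__ import annotations

import numpy as np

from ._rng import spawn_rngs
from .groundtruth import GroundTruth

__all__ = ["generate_puncta_image", "disk_mask"]


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def generate_puncta_image(
    n_puncta: int,
    region_mask: np.ndarray | None = None,
    shape: tuple[int, int] = (256, 256),
    punctum_radius: float = 3.0,
    background: float = 0.1,
    amplitude: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Micrograph with ``n_puncta`` planted disks inside ``region_mask``.

    Raises ValueError when the mask cannot host the requested number of
    non-overlapping puncta.  Returns (image, ground truth); the planted
    centers are echoed in the ground-truth params.
    """
    if n_puncta < 0:
        raise ValueError("n_puncta must be non-negative")
    if region_mask is None:
        region_mask = np.ones(shape, dtype=bool)
    else:
        region_mask = np.asarray(region_mask, dtype=bool)
        shape = region_mask.shape
    (rng,) = spawn_rngs(seed, 1)
    r = punctum_radius
    min_sep = 2 * r + 2
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = max(1000, 1000 * n_puncta)
    ys, xs = np.nonzero(region_mask)
    if n_puncta > 0 and len(ys) == 0:
        raise ValueError("empty region mask")
    while len(centers) < n_puncta:
        if attempts >= max_attempts:
            raise ValueError(
                "mask too small for the requested non-overlapping puncta"
            )
        attempts += 1
        k = rng.integers(len(ys))
        cy, cx = float(ys[k]), float(xs[k])
        if cy < r + 1 or cx < r + 1 or cy > shape[0] - r - 2 or cx > shape[1] - r - 2:
            continue
        if any((cy - y) ** 2 + (cx - x) ** 2 < min_sep**2 for y, x in centers):
            continue
        d = disk_mask(shape, (cy, cx), r)
        if not region_mask[d].all():
            continue
        centers.append((cy, cx))
    image = np.full(shape, background, dtype=float)
    for c in centers:
        image[disk_mask(shape, c, r)] = background + amplitude
    if noise_sd > 0:
        image = image + rng.normal(0, noise_sd, shape)
    gt = GroundTruth(
        modality="puncta",
        params={
            "punctum_radius": punctum_radius,
            "background": background,
            "amplitude": amplitude,
            "noise_sd": noise_sd,
            "centers": [list(c) for c in centers],
            "seed": seed,
        },
        puncta_count=n_puncta,
        region_area_px=int(region_mask.sum()),
    )
    return image, gt
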