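"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementations: episode
segmentation by exhaustive interval enumeration, connected components
by flood fill, Spearman by hand-rolled ranks, and step counting by raw
sign changes.  They are slow and simple on purpose.
"""

from __future__ import annotations

from collections import deque
from functools import lru_cache
from itertools import permutations

import numpy as np


def brute_force_episodes(
    time: np.ndarray,
    ppd: np.ndarray,
    azimuth: np.ndarray,
    capture_ppd: float = 3.0,
    jitter_tol: float = 0.5,
    azimuth_limit: float = 90.0,
    min_gap: float = 0.5,
    min_duration: float = 0.2,
) -> list[tuple[int, int]]:
    """Exhaustive approach-episode scan; returns (start, end) frame indices.

    Same episode definition as the analysis module, computed the slow
    way: every candidate interval is re-checked from scratch against
    both criteria (azimuth within limits throughout; no sample above
    the running PPD minimum by more than the jitter tolerance).
    """
    n = len(ppd)
    az_ok = np.isfinite(azimuth) & (np.abs(azimuth) <= azimuth_limit)
    finite = np.isfinite(ppd)

    def interval_ok(i: int, e: int) -> bool:
        if not np.all(az_ok[i : e + 1]) or not np.all(finite[i : e + 1]):
            return False
        seg = ppd[i : e + 1]
        return bool(np.all(seg - np.minimum.accumulate(seg) <= jitter_tol))

    raw: list[tuple[int, int]] = []
    last_end = -1
    for e in range(n):
        if not (
            e > last_end
            and e > 0
            and finite[e]
            and finite[e - 1]
            and az_ok[e]
            and ppd[e] < capture_ppd
            and ppd[e - 1] >= capture_ppd
        ):
            continue
        i_best = None
        for i in range(e, last_end, -1):
            if interval_ok(i, e):
                i_best = i
            else:
                break
        seg = ppd[i_best : e + 1]
        top = seg.max()
        start = i_best + max(k for k in range(len(seg)) if seg[k] == top)
        raw.append((start, e))
        last_end = e
    merged: list[list[int]] = []
    for s, e in raw:
        bridge_ok = merged and all(
            az_ok[k] and finite[k] for k in range(merged[-1][1], s + 1)
        )
        if merged and time[s] - time[merged[-1][1]] < min_gap and bridge_ok:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if time[e] - time[s] >= min_duration]


def flood_fill_count(
    binary: np.ndarray,
    mask: np.ndarray,
    min_area: int = 1,
    max_area: int | None = None,
) -> int:
    """8-connected component count (size-gated, mask-intersecting) by BFS."""
    h, w = binary.shape
    visited = np.zeros_like(binary, dtype=bool)
    count = 0
    for y0 in range(h):
        for x0 in range(w):
            if not binary[y0, x0] or visited[y0, x0]:
                continue
            comp = []
            queue = deque([(y0, x0)])
            visited[y0, x0] = True
            while queue:
                y, x = queue.popleft()
                comp.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and binary[yy, xx] and not visited[yy, xx]:
                            visited[yy, xx] = True
                            queue.append((yy, xx))
            size_ok = len(comp) >= min_area and (max_area is None or len(comp) <= max_area)
            if size_ok and any(mask[y, x] for y, x in comp):
                count += 1
    return count


def spearman_bruteforce(x, y) -> float:
    """Spearman rho from first principles (average ranks for ties)."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den if den else float("nan")


@lru_cache(maxsize=8)
def exact_abs_rho_null(n: int) -> np.ndarray:
    """All |rho| values of untied rank permutations of size n (n <= 9)."""
    if n > 9:
        raise ValueError("enumeration limited to n <= 9")
    base = np.arange(1, n + 1)
    perms = np.array(list(permutations(base)))
    d2 = ((perms - base) ** 2).sum(axis=1)
    rho = 1 - 6 * d2 / (n * (n**2 - 1))
    return np.abs(rho)


def null_band_edge(n: int, coverage: float = 0.95) -> float:
    """Smallest q with P(|rho| <= q) >= coverage under the exact null."""
    vals = np.sort(exact_abs_rho_null(n))
    k = int(np.ceil(coverage * len(vals))) - 1
    return float(vals[k])


def count_sign_change_steps(rel_velocity: np.ndarray) -> int:
    """Stance onsets as raw +->- sign changes of body-frame paw velocity."""
    s = np.sign(rel_velocity)
    return int(np.sum((s[:-1] > 0) & (s[1:] < 0)))
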