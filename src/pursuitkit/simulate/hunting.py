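"""Synthetic predatory-hunting trials with planted approach episodes.

The generator constructs a predator/prey trajectory from an explicit
behavioral script so that every planted approach episode satisfies the
two segmentation criteria exactly (at zero noise) and nothing else
does:

* **approach**: the predator pursues the fleeing prey in a straight
  chase at a constant planted speed (the episode's peak speed), head
  toward the prey (azimuth 0), so the predator-prey distance falls
  strictly monotonically until contact;
* **contact**: the pair drifts together below the 3-cm attack distance
  for a short dwell during which jaw attacks are emitted as a Poisson
  process;
* **inter-episode gap**: the prey performs a bounded random walk while
  the predator retreats to the next start distance with its head
  pointing directly away from the prey, so the azimuth criterion is
  violated on every gap frame.

Wild-type trials contain 10-20 approach episodes; the capture time is
the last jaw attack, which the generator forces at the end of the last
contact dwell.  Gaussian position noise of configurable SD is added to
every tracked point.  Identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..hunting import AttackLog
from ..kinematics import Trajectory
from ._rng import spawn_rngs
from .groundtruth import GroundTruth

__all__ = ["PursuitParams", "generate_hunting_trial"]


@dataclass
class PursuitParams:
    """Parameters of a synthetic hunting trial.

    ``n_episodes=None`` draws the episode count uniformly from 10-20,
    the range observed in wild-type trials.  ``approach_peak_speeds``
    (cm/s, one per episode) defaults to uniform draws from
    ``peak_speed_range``.  Attacks are emitted at ``attack_rate`` while
    the predator-prey distance is below ``attack_ppd``.
    """

    frame_rate: float = 50.0
    arena_size: tuple[float, float] = (40.0, 40.0)
    n_episodes: int | None = None
    approach_peak_speeds: np.ndarray | None = None
    peak_speed_range: tuple[float, float] = (20.0, 30.0)
    start_ppd_range: tuple[float, float] = (14.0, 20.0)
    inter_episode_gap: float = 2.0
    attack_ppd: float = 3.0
    attack_rate: float = 1.0
    contact_dwell: float = 0.6
    contact_ppd: float = 2.0
    prey_flee_speed: float = 4.0
    prey_walk_speed: float = 2.0
    retreat_speed_max: float = 15.0
    head_length: float = 2.0
    position_noise_sd: float = 0.0
    max_duration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_episodes is not None and self.n_episodes < 0:
            raise ValueError("n_episodes must be non-negative")
        if self.approach_peak_speeds is not None:
            self.approach_peak_speeds = np.asarray(self.approach_peak_speeds, float)
            if np.any(self.approach_peak_speeds <= 0):
                raise ValueError("peak speeds must be positive")
            if self.n_episodes is None:
                self.n_episodes = len(self.approach_peak_speeds)
            elif self.n_episodes != len(self.approach_peak_speeds):
                raise ValueError("one peak speed per planned episode required")
        if self.prey_flee_speed >= self.peak_speed_range[0] and (
            self.approach_peak_speeds is None
            or self.prey_flee_speed >= self.approach_peak_speeds.min()
        ):
            raise ValueError("prey flee speed must be below the approach speed")


class _Builder:
    """Accumulates per-frame positions; head stored as a unit direction."""

    def __init__(self, params: PursuitParams):
        self.p = params
        self.dt = 1.0 / params.frame_rate
        self.pred: list[np.ndarray] = []
        self.prey: list[np.ndarray] = []
        self.head_dir: list[np.ndarray] = []

    def add(self, pred, prey, head_dir):
        self.pred.append(np.asarray(pred, float))
        self.prey.append(np.asarray(prey, float))
        self.head_dir.append(np.asarray(head_dir, float))

    @property
    def n(self) -> int:
        return len(self.pred)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0])


def _walk_prey(prey: np.ndarray, rng, params: PursuitParams, n_frames: int):
    """Bounded random walk: smooth heading, reflected off a margin box."""
    lo = 8.0
    hi_x = params.arena_size[0] - 8.0
    hi_y = params.arena_size[1] - 8.0
    dt = 1.0 / params.frame_rate
    ang = rng.uniform(0, 2 * np.pi)
    out = np.empty((n_frames, 2))
    pos = prey.copy()
    for i in range(n_frames):
        ang += rng.normal(0, 0.4)
        step = params.prey_walk_speed * dt * np.array([np.cos(ang), np.sin(ang)])
        nxt = pos + step
        if not (lo <= nxt[0] <= hi_x and lo <= nxt[1] <= hi_y):
            ang += np.pi
            nxt = pos
        pos = nxt
        out[i] = pos
    return out


def generate_hunting_trial(
    params: PursuitParams,
) -> tuple[Trajectory, AttackLog, GroundTruth]:
    """Build one synthetic hunting trial.

    Returns the tracked trajectory (predator centroid + head point,
    prey centroid), the jaw-attack log, and the ground truth: planted
    episode intervals (approach start to the first frame below 3 cm),
    per-episode peak speeds, attack times, and the capture time.
    """
    p = params
    rng_geom, rng_prey, rng_attack, rng_noise = spawn_rngs(p.seed, 4)
    dt = 1.0 / p.frame_rate
    n_ep = p.n_episodes
    if n_ep is None:
        n_ep = int(rng_geom.integers(10, 21))
    speeds = p.approach_peak_speeds
    if speeds is None:
        speeds = rng_geom.uniform(*p.peak_speed_range, size=n_ep)
    center = np.array(p.arena_size) / 2.0

    b = _Builder(p)
    gt_intervals: list[tuple[float, float]] = []
    gt_peaks: list[float] = []
    attack_frames: list[int] = []

    pred = center.copy()
    prey = center + np.array([12.0, 0.0])

    def gap_segment(duration: float, d0: float | None):
        """Prey walks; predator retreats to distance d0 (head away from prey)."""
        nonlocal pred, prey
        n_frames = max(1, int(round(duration / dt)))
        prey_path = _walk_prey(prey, rng_prey, p, n_frames)
        if d0 is None:
            target = pred.copy()
        else:
            # retreat target at distance d0 from the prey's final position,
            # rejected into the central box so the chase stays in-arena
            for _ in range(200):
                ang = rng_geom.uniform(0, 2 * np.pi)
                target = prey_path[-1] + d0 * np.array([np.cos(ang), np.sin(ang)])
                if (6.0 <= target[0] <= p.arena_size[0] - 6.0) and (
                    6.0 <= target[1] <= p.arena_size[1] - 6.0
                ):
                    break
        dist = np.linalg.norm(target - pred)
        if dist / (n_frames * dt) > p.retreat_speed_max:
            n_frames = int(np.ceil(dist / p.retreat_speed_max / dt))
            prey_path = _walk_prey(prey, rng_prey, p, n_frames)
        path = pred + np.linspace(0, 1, n_frames + 1)[1:, None] * (target - pred)
        for i in range(n_frames):
            away = _unit(path[i] - prey_path[i])
            b.add(path[i], prey_path[i], away)
        pred, prey = path[-1].copy(), prey_path[-1].copy()

    def approach_segment(v: float):
        """Straight chase at speed v until contact; returns episode interval."""
        nonlocal pred, prey
        start_frame = b.n
        cross_frame = None
        guard = 0
        while True:
            to_prey = _unit(prey - pred)
            b.add(pred, prey, to_prey)
            d = np.linalg.norm(prey - pred)
            if cross_frame is None and d < p.attack_ppd:
                cross_frame = b.n - 1
            if d < p.attack_ppd:
                attack_window_frames.append(b.n - 1)
            if d <= p.contact_ppd:
                break
            flee = _unit(prey - pred)
            prey = prey + p.prey_flee_speed * dt * flee
            pred = pred + v * dt * _unit(prey - pred)
            guard += 1
            if guard > 100000:  # pragma: no cover - construction safeguard
                raise RuntimeError("approach failed to converge")
        return start_frame, cross_frame

    def dwell_segment():
        """Predator tracks the prey below attack distance (jaw attacks)."""
        nonlocal pred, prey
        n_frames = max(1, int(round(p.contact_dwell / dt)))
        flee = _unit(prey - pred)
        for _ in range(n_frames):
            prey = prey + p.prey_flee_speed * dt * flee
            pred = pred + p.prey_flee_speed * dt * flee
            b.add(pred, prey, _unit(prey - pred))
            attack_window_frames.append(b.n - 1)

    attack_window_frames: list[int] = []

    if n_ep == 0:
        # nothing moves: prey parked far away, predator idle at center
        prey = np.array([p.arena_size[0] - 5.0, p.arena_size[1] - 5.0])
        n_frames = int(round(5.0 / dt))
        for _ in range(n_frames):
            b.add(pred, prey, _unit(pred - prey))
    else:
        gap_segment(p.inter_episode_gap, float(rng_geom.uniform(*p.start_ppd_range)))
        for k in range(n_ep):
            s, c = approach_segment(float(speeds[k]))
            gt_intervals.append((s * dt, c * dt))
            gt_peaks.append(float(speeds[k]))
            dwell_segment()
            if k < n_ep - 1:
                d0 = float(rng_geom.uniform(*p.start_ppd_range))
                gap_segment(p.inter_episode_gap, d0)
        # quiet tail so the last speed bin is complete
        tail = int(round(1.0 / dt))
        for _ in range(tail):
            b.add(pred, prey, _unit(pred - prey))

    # attacks: Poisson thinning over the sub-3-cm frames
    attack_frames = [
        f for f in attack_window_frames if rng_attack.random() < p.attack_rate * dt
    ]
    capture_time = None
    if n_ep > 0:
        last_contact = attack_window_frames[-1]
        if not attack_frames or attack_frames[-1] != last_contact:
            attack_frames.append(last_contact)
        capture_time = last_contact * dt
    attack_times = np.array(sorted(set(attack_frames))) * dt

    n = b.n
    time = np.arange(n) * dt
    if p.max_duration is not None and time[-1] > p.max_duration:
        raise ValueError("planned episodes do not fit in max_duration")
    pred_xy = np.asarray(b.pred)
    prey_xy = np.asarray(b.prey)
    head_xy = pred_xy + p.head_length * np.asarray(b.head_dir)
    if p.position_noise_sd > 0:
        pred_xy = pred_xy + rng_noise.normal(0, p.position_noise_sd, pred_xy.shape)
        head_xy = head_xy + rng_noise.normal(0, p.position_noise_sd, head_xy.shape)
        prey_xy = prey_xy + rng_noise.normal(0, p.position_noise_sd, prey_xy.shape)

    traj = Trajectory(
        time=time,
        predator=pred_xy,
        head=head_xy,
        prey=prey_xy,
        arena_size=p.arena_size,
    )
    attacks = AttackLog(attack_times=attack_times, prey_intro_time=0.0)
    gt = GroundTruth(
        modality="hunting",
        params={
            "frame_rate": p.frame_rate,
            "n_episodes": n_ep,
            "inter_episode_gap": p.inter_episode_gap,
            "attack_rate": p.attack_rate,
            "position_noise_sd": p.position_noise_sd,
            "seed": p.seed,
        },
        episode_intervals=[(float(a), float(bb)) for a, bb in gt_intervals],
        episode_peak_speeds=[float(v) for v in gt_peaks],
        attack_times=[float(t) for t in attack_times],
        capture_time=capture_time,
    )
    return traj, attacks, gt
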