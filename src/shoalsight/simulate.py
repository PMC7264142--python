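"""Agent-based synthetic shoal: zonal schooling, stimulus protocol, detection.

The generator emulates the experiment the analysis pipeline was built for:
eight fish in a 133.5 x 72 cm oval arena filmed at 25 fps, with up to six
stimulus presentations per trial at wall ports, each presented only when
the whole group is at least 43 cm away on the opposite half of the arena.

Movement follows the standard zonal scheme: repulsion from very close
neighbours takes absolute priority; otherwise a weighted blend of
alignment with neighbours (weight ``w_align`` — the single knob that
controls group polarization), attraction towards neighbours, and wall
avoidance, plus Gaussian heading noise.  Speeds are per-fish constants
drawn once per simulation.

Detection of the stimulus is hazard-based and mirrors the study's
private/social information mechanism:

* *private*: a non-responding fish whose binocular field contains the port
  (and whose sight line is not occluded by a groupmate's body) detects
  with per-frame hazard ``h0 * exp(-d / lam)``;
* *social*: a fish that can see already-responding groupmates responds
  with hazard ``s0 * n_visible_responders * (1 + gamma * P)`` — the
  alignment gain ``(1 + gamma * P)`` encodes faster transfer of social
  information in polarized groups.

Responders steer straight to the port at a goal-speed multiple of their
cruise speed; ground truth (channel, detection frame, arrival frame) is
logged per fish per presentation, so event-detection and inference layers
can be scored against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arena import ArenaGeometry, default_arena
from .events import MAX_WINDOW_FRAMES, MIN_DIST_MM, Presentation
from .io import TrajectorySet
from .vision import VisionConfig

__all__ = [
    "SimConfig",
    "DetectionModel",
    "SimOutput",
    "simulate_shoal",
    "run_presentation_protocol",
    "apply_detection_model",
    "simulate_experiment",
    "calibrate_polarization",
]


@dataclass(frozen=True)
class SimConfig:
    n_fish: int = 8
    fps: float = 25.0
    arena: ArenaGeometry = field(default_factory=default_arena)
    r_repulsion_mm: float = 60.0
    r_align_mm: float = 250.0
    r_attract_mm: float = 600.0
    w_align: float = 1.5
    w_attract: float = 1.0
    w_wall: float = 1.5
    wall_avoid_mm: float = 100.0
    turn_rate: float = 0.4  # blending rate of heading towards desired direction
    heading_noise_sd_deg: float = 8.0
    speed_mean_mm_per_frame: float = 2.0  # ~50 mm/s cruise
    speed_sd_mm_per_frame: float = 0.4
    body_length_mean_mm: float = 27.0
    body_length_sd_mm: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.r_repulsion_mm < self.r_align_mm < self.r_attract_mm):
            raise ValueError("zone radii must satisfy repulsion < alignment < attraction")
        if self.heading_noise_sd_deg < 0:
            raise ValueError("heading noise SD must be non-negative")


@dataclass(frozen=True)
class DetectionModel:
    h0: float = 0.05  # private hazard scale, frame^-1
    lam_mm: float = 800.0  # private hazard distance constant
    s0: float = 0.015  # social hazard per visible responder, frame^-1
    gamma: float = 2.0  # alignment gain slope: g(P) = 1 + gamma * P
    goal_speed_multiplier: float = 3.0

    def alignment_gain(self, pol: float) -> float:
        return 1.0 + self.gamma * max(0.0, min(1.0, pol))

    def private_hazard(self, dist_mm: float) -> float:
        return min(1.0, self.h0 * math.exp(-dist_mm / self.lam_mm))

    def social_hazard(self, n_visible_responders: int, pol: float) -> float:
        return min(1.0, self.s0 * n_visible_responders * self.alignment_gain(pol))


@dataclass
class SimOutput:
    traj: TrajectorySet
    headings_true: np.ndarray  # (n_fish, n_frames) heading angles, radians
    presentations: list[Presentation]
    truth: pd.DataFrame  # presentation_id, fish_id, channel, detect_frame, arrival_frame


# ---------------------------------------------------------------------------
# engine

class _Engine:
    """Mutable simulation state advanced one frame at a time."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        n = config.n_fish
        arena = config.arena
        # spawn in a loose cluster near a random interior point
        for _ in range(200):
            centre = rng.uniform([-arena.length_mm / 4, -arena.width_mm / 4],
                                 [arena.length_mm / 4, arena.width_mm / 4])
            pos = centre + rng.normal(scale=80.0, size=(n, 2))
            if np.all(arena.signed_distance(pos) < -30):
                break
        self.pos = pos
        self.theta = rng.uniform(-math.pi, math.pi, size=n)
        self.cruise = np.clip(
            rng.normal(config.speed_mean_mm_per_frame, config.speed_sd_mm_per_frame, n),
            0.5, None,
        )
        self.body_length = np.clip(
            rng.normal(config.body_length_mean_mm, config.body_length_sd_mm, n),
            15.0, None,
        )
        self.goal: np.ndarray | None = None  # per-fish port target or NaN
        self.goal_speed = self.cruise.copy()

    @property
    def headings(self) -> np.ndarray:
        return np.stack([np.cos(self.theta), np.sin(self.theta)], axis=1)

    def polarization(self) -> float:
        return float(np.linalg.norm(self.headings.mean(axis=0)))

    def step(self) -> None:
        cfg = self.cfg
        n = cfg.n_fish
        pos, h = self.pos, self.headings
        diff = pos[None, :, :] - pos[:, None, :]  # diff[i, j] = x_j - x_i
        dist = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(dist, np.inf)
        with np.errstate(invalid="ignore"):
            unit = diff / np.maximum(dist, 1e-9)[:, :, None]

        rep_mask = dist < cfg.r_repulsion_mm
        align_mask = (dist >= cfg.r_repulsion_mm) & (dist < cfg.r_align_mm)
        attract_mask = (dist >= cfg.r_repulsion_mm) & (dist < cfg.r_attract_mm)

        rep_dir = -(unit * rep_mask[:, :, None]).sum(axis=1)
        align_dir = (h[None, :, :] * align_mask[:, :, None]).sum(axis=1)
        attract_dir = (unit * attract_mask[:, :, None]).sum(axis=1)

        def _norm(v: np.ndarray) -> np.ndarray:
            nv = np.linalg.norm(v, axis=1, keepdims=True)
            return np.where(nv > 1e-9, v / np.maximum(nv, 1e-9), 0.0)

        desired = cfg.w_align * _norm(align_dir) + cfg.w_attract * _norm(attract_dir)
        has_rep = rep_mask.any(axis=1)
        desired[has_rep] = _norm(rep_dir)[has_rep]

        # wall avoidance ramps up within wall_avoid_mm of the boundary
        sd = self.cfg.arena.signed_distance(pos)
        near = sd > -cfg.wall_avoid_mm
        if near.any():
            inward = self.cfg.arena.inward_normal_at(pos[near])
            strength = cfg.w_wall * (1.0 + sd[near] / cfg.wall_avoid_mm)
            desired[near] += strength[:, None] * inward

        speed = self.cruise.copy()
        if self.goal is not None:
            going = ~np.isnan(self.goal[:, 0])
            if going.any():
                to_goal = _norm(self.goal[going] - pos[going])
                desired[going] = 2.0 * to_goal + 0.5 * desired[going]
                speed[going] = self.goal_speed[going]

        new_h = _norm(h + cfg.turn_rate * _norm(desired))
        zero = np.linalg.norm(new_h, axis=1) < 1e-9
        new_h[zero] = h[zero]
        theta = np.arctan2(new_h[:, 1], new_h[:, 0])
        theta += np.deg2rad(cfg.heading_noise_sd_deg) * self.rng.standard_normal(n)

        step = np.stack([np.cos(theta), np.sin(theta)], axis=1) * speed[:, None]
        new_pos = pos + step
        # reflective boundary handling: push offenders back inside and
        # reflect the outward heading component
        out = self.cfg.arena.signed_distance(new_pos) > -2.0
        if out.any():
            inward = self.cfg.arena.inward_normal_at(new_pos[out])
            depth = self.cfg.arena.signed_distance(new_pos[out]) + 2.0
            new_pos[out] += inward * depth[:, None]
            hdir = np.stack([np.cos(theta[out]), np.sin(theta[out])], axis=1)
            dot = np.einsum("ij,ij->i", hdir, inward)
            refl = hdir - 2 * np.minimum(dot, 0.0)[:, None] * inward
            theta[out] = np.arctan2(refl[:, 1], refl[:, 0])
        self.pos = new_pos
        self.theta = theta


def _as_trajectory(config: SimConfig, pos_hist: np.ndarray, body_length: np.ndarray,
                   group_id: str) -> TrajectorySet:
    n_frames = pos_hist.shape[0]
    return TrajectorySet(
        group_id=group_id,
        fish_ids=list(range(1, config.n_fish + 1)),
        frames=np.arange(n_frames),
        positions=np.transpose(pos_hist, (1, 0, 2)),
        body_length_mm=body_length,
    )


def simulate_shoal(
    config: SimConfig, n_frames: int = 3000, group_id: str = "sim"
) -> tuple[TrajectorySet, np.ndarray]:
    """Plain schooling run; returns the trajectory and true heading angles."""
    rng = np.random.default_rng(config.seed)
    eng = _Engine(config, rng)
    pos_hist = np.empty((n_frames, config.n_fish, 2))
    theta_hist = np.empty((n_frames, config.n_fish))
    for t in range(n_frames):
        pos_hist[t] = eng.pos
        theta_hist[t] = eng.theta
        eng.step()
    traj = _as_trajectory(config, pos_hist, eng.body_length, group_id)
    return traj, theta_hist.T


def _eligible(pos: np.ndarray, port: np.ndarray, min_dist_mm: float) -> bool:
    if np.any(np.linalg.norm(pos - port, axis=1) < min_dist_mm):
        return False
    side = np.sign(port[0])
    return side == 0 or not np.any(np.sign(pos[:, 0]) == side)


def run_presentation_protocol(
    traj: TrajectorySet,
    config: SimConfig,
    n_presentations: int = 6,
    min_gap_s: float = 180.0,
    min_dist_mm: float = MIN_DIST_MM,
    rng: np.random.Generator | None = None,
    trial_id: str = "sim",
) -> list[Presentation]:
    """Select presentation onsets on an existing trajectory.

    When the minimum gap since the previous presentation has elapsed, a
    port is drawn uniformly and held until the whole group is on the
    opposite half and beyond ``min_dist_mm``; the first such frame is the
    onset.  Fewer than ``n_presentations`` may fit (a warning is logged).
    """
    import logging

    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    ports = config.arena.ports
    if not ports:
        raise ValueError("arena has no stimulus ports")
    min_gap = int(round(min_gap_s * config.fps))
    pres: list[Presentation] = []
    next_allowed = 0
    port = ports[rng.integers(len(ports))]
    earliest = 13  # need a full pre-stimulus window
    for t in range(earliest, traj.n_frames - 1):
        if t < next_allowed:
            continue
        pos = traj.positions[:, t]
        if np.isnan(pos).any():
            continue
        if _eligible(pos, np.asarray(port.position), min_dist_mm):
            pres.append(Presentation(trial_id, len(pres) + 1, int(traj.frames[t]), port))
            if len(pres) >= n_presentations:
                break
            next_allowed = t + min_gap
            port = ports[rng.integers(len(ports))]
    if len(pres) < n_presentations:
        logging.getLogger("shoalsight").warning(
            "only %d of %d presentations fitted in %d frames",
            len(pres), n_presentations, traj.n_frames,
        )
    return pres


# ---------------------------------------------------------------------------
# fast vectorized occlusion used inside the simulation loop

def _segments_blocked(
    origins: np.ndarray,
    targets: np.ndarray,
    centres: np.ndarray,
    angles: np.ndarray,
    semi_major: np.ndarray,
    semi_minor: np.ndarray,
    exclude: np.ndarray,
) -> np.ndarray:
    """Blocked flag for k sight lines against m ellipses (vectorized).

    ``exclude`` is a (k, m) boolean of ellipses to ignore per segment
    (the viewer's own body, the viewed fish's body).
    """
    d = targets - origins
    lens = np.linalg.norm(d, axis=1)
    u = d / np.maximum(lens, 1e-12)[:, None]
    c, s = np.cos(angles), np.sin(angles)
    # into each ellipse frame
    rel = origins[:, None, :] - centres[None, :, :]
    ox = (rel[..., 0] * c + rel[..., 1] * s) / semi_major
    oy = (-rel[..., 0] * s + rel[..., 1] * c) / semi_minor
    dx = (u[:, None, 0] * c + u[:, None, 1] * s) / semi_major
    dy = (-u[:, None, 0] * s + u[:, None, 1] * c) / semi_minor
    a = dx**2 + dy**2
    b = ox * dx + oy * dy
    cc = ox**2 + oy**2 - 1.0
    disc = b**2 - a * cc
    with np.errstate(invalid="ignore", divide="ignore"):
        sq = np.sqrt(np.maximum(disc, 0.0))
        t1 = (-b - sq) / a
        t2 = (-b + sq) / a
    t = np.where(t1 > 1e-9, t1, np.where(t2 > 1e-9, t2, np.inf))
    t[disc < 0] = np.inf
    t[exclude] = np.inf
    return (t < lens[:, None]).any(axis=1)


def _in_sector(eye: np.ndarray, theta: np.ndarray, point: np.ndarray,
               half_angle: float) -> np.ndarray:
    rel = point[None, :] - eye
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    dang = (ang - theta + math.pi) % (2 * math.pi) - math.pi
    return np.abs(dang) <= half_angle


def apply_detection_model(
    config: SimConfig,
    model: DetectionModel = DetectionModel(),
    vision: VisionConfig = VisionConfig(),
    n_presentations: int = 6,
    min_gap_s: float = 180.0,
    n_frames: int | None = None,
    warmup_frames: int = 250,
    group_id: str = "sim",
    trial_id: str = "sim",
    cumulative_days: int = 0,
) -> SimOutput:
    """Full experiment: schooling, online presentations, hazard detection.

    Runs the engine forward; when the protocol's gap has elapsed and the
    group is eligible for the currently drawn port, the stimulus appears.
    During the 500-frame window, non-responders test a private hazard
    (binocular sight of the port required) then a social hazard (scaled by
    visible responding groupmates and the alignment gain); responders dash
    to the port.  The window closes when every fish has arrived or 500
    frames elapse; everyone then resumes schooling.

    Ground truth per (presentation, fish): ``channel`` in
    {private, social, none}, detection frame and arrival frame.
    """
    rng = np.random.default_rng(config.seed)
    eng = _Engine(config, rng)
    min_gap = int(round(min_gap_s * config.fps))
    budget = n_frames if n_frames is not None else warmup_frames + n_presentations * (
        min_gap + MAX_WINDOW_FRAMES + 1500)

    n = config.n_fish
    bin_half = vision.field_half_angle("binocular")
    full_half = vision.field_half_angle("full")
    semi_major = eng.body_length / 2.0
    semi_minor = vision.body_aspect * eng.body_length / 2.0
    eye_off = vision.eye_offset_bl * eng.body_length

    pos_hist = np.empty((budget, n, 2))
    theta_hist = np.empty((budget, n))
    presentations: list[Presentation] = []
    truth_rows: list[dict] = []

    ports = config.arena.ports
    if not ports:
        raise ValueError("arena has no stimulus ports")
    port = ports[rng.integers(len(ports))]
    next_allowed = warmup_frames
    in_window = False
    onset = -1
    responded = np.zeros(n, dtype=bool)
    channel = np.array(["none"] * n, dtype=object)
    detect_frame = np.full(n, -1)
    arrival_frame = np.full(n, -1)

    def _close_window(pid: int) -> None:
        for i in range(n):
            truth_rows.append(
                {
                    "presentation_id": pid,
                    "fish_id": i + 1,
                    "channel": channel[i],
                    "detect_frame": int(detect_frame[i]) if detect_frame[i] >= 0 else None,
                    "arrival_frame": int(arrival_frame[i]) if arrival_frame[i] >= 0 else None,
                }
            )

    t = 0
    while t < budget:
        pos_hist[t] = eng.pos
        theta_hist[t] = eng.theta

        if in_window:
            port_xy = np.asarray(port.position)
            eyes = eng.pos + eye_off[:, None] * eng.headings
            pol = eng.polarization()
            dists = np.linalg.norm(eng.pos - port_xy, axis=1)
            # arrivals: within two body lengths of the port
            arrived_now = (dists <= 2 * eng.body_length) & (arrival_frame < 0)
            arrival_frame[arrived_now] = t - onset
            if arrived_now.any() and eng.goal is not None:
                eng.goal_speed[arrived_now] = eng.cruise[arrived_now]

            nonresp = np.flatnonzero(~responded)
            if nonresp.size:
                self_excl = np.zeros((nonresp.size, n), dtype=bool)
                self_excl[np.arange(nonresp.size), nonresp] = True
                # private: port inside the binocular sector, line unoccluded
                sees_angle = _in_sector(eyes[nonresp], eng.theta[nonresp], port_xy, bin_half)
                blocked = _segments_blocked(
                    eyes[nonresp], np.broadcast_to(port_xy, (nonresp.size, 2)),
                    eng.pos, eng.theta, semi_major, semi_minor, self_excl,
                )
                sees_port = sees_angle & ~blocked
                u = rng.random(nonresp.size)
                hazards = np.array([model.private_hazard(dists[i]) for i in nonresp])
                priv = sees_port & (u < hazards)
                # social: responders visible within the full field
                resp_idx = np.flatnonzero(responded)
                n_vis = np.zeros(nonresp.size, dtype=int)
                if resp_idx.size:
                    # all (viewer, responder) pairs in one vectorized pass
                    vi = np.repeat(nonresp, resp_idx.size)
                    rj = np.tile(resp_idx, nonresp.size)
                    rel = eng.pos[rj] - eyes[vi]
                    ang = np.arctan2(rel[:, 1], rel[:, 0])
                    dang = (ang - eng.theta[vi] + math.pi) % (2 * math.pi) - math.pi
                    in_field = np.abs(dang) <= full_half
                    excl = np.zeros((vi.size, n), dtype=bool)
                    excl[np.arange(vi.size), vi] = True
                    excl[np.arange(vi.size), rj] = True
                    blk = _segments_blocked(
                        eyes[vi], eng.pos[rj],
                        eng.pos, eng.theta, semi_major, semi_minor, excl,
                    )
                    vis = (in_field & ~blk).reshape(nonresp.size, resp_idx.size)
                    n_vis = vis.sum(axis=1)
                u2 = rng.random(nonresp.size)
                soc = (~priv) & (n_vis > 0) & (
                    u2 < np.array([model.social_hazard(v, pol) for v in n_vis])
                )
                new_resp = nonresp[priv | soc]
                for k, i in enumerate(nonresp):
                    if priv[k]:
                        channel[i] = "private"
                    elif soc[k]:
                        channel[i] = "social"
                    else:
                        continue
                    detect_frame[i] = t - onset
                responded[new_resp] = True
                if new_resp.size:
                    if eng.goal is None:
                        eng.goal = np.full((n, 2), np.nan)
                    eng.goal[new_resp] = port_xy
                    eng.goal_speed[new_resp] = (
                        model.goal_speed_multiplier * eng.cruise[new_resp]
                    )

            if (t - onset >= MAX_WINDOW_FRAMES) or (arrival_frame >= 0).all():
                _close_window(presentations[-1].presentation_id)
                in_window = False
                eng.goal = None
                eng.goal_speed = eng.cruise.copy()
                next_allowed = t + min_gap
                port = ports[rng.integers(len(ports))]
        elif (
            len(presentations) < n_presentations
            and t >= next_allowed
            and _eligible(eng.pos, np.asarray(port.position), MIN_DIST_MM)
        ):
            onset = t
            in_window = True
            responded[:] = False
            channel[:] = "none"
            detect_frame[:] = -1
            arrival_frame[:] = -1
            presentations.append(
                Presentation(trial_id, len(presentations) + 1, t, port,
                             cumulative_days_of_testing=cumulative_days)
            )

        eng.step()
        t += 1
        if len(presentations) >= n_presentations and not in_window:
            break

    n_used = t
    traj = _as_trajectory(config, pos_hist[:n_used], eng.body_length, group_id)
    truth = pd.DataFrame(
        truth_rows,
        columns=["presentation_id", "fish_id", "channel", "detect_frame", "arrival_frame"],
    )
    return SimOutput(traj, theta_hist[:n_used].T, presentations, truth)


def simulate_experiment(config: SimConfig, **kwargs) -> SimOutput:
    """Alias for :func:`apply_detection_model` with default model settings."""
    return apply_detection_model(config, **kwargs)


def mean_polarization(config: SimConfig, n_frames: int = 3000,
                      warmup: int = 300) -> float:
    """Mean instantaneous polarization of a schooling run (after warm-up)."""
    rng = np.random.default_rng(config.seed)
    eng = _Engine(config, rng)
    for _ in range(warmup):
        eng.step()
    acc = 0.0
    for _ in range(n_frames):
        eng.step()
        acc += eng.polarization()
    return acc / n_frames


def calibrate_polarization(
    target: float,
    template: SimConfig = SimConfig(),
    tol: float = 0.05,
    n_frames: int = 3000,
    w_align_bracket: tuple[float, float] = (-4.0, 10.0),
    max_iter: int = 20,
) -> SimConfig:
    """Bisection on ``w_align`` until the run-mean polarization hits ``target``.

    Heading noise stays fixed; only the alignment weight moves.  Raises if
    the target is outside (0.05, 0.98) or outside the achievable bracket.
    """
    if not (0.05 < target < 0.98):
        raise ValueError("target polarization must be in (0.05, 0.98)")
    lo, hi = w_align_bracket

    def _eval(w: float) -> float:
        return mean_polarization(replace(template, w_align=w), n_frames=n_frames)

    p_lo, p_hi = _eval(lo), _eval(hi)
    if not (p_lo - tol <= target <= p_hi + tol):
        raise ValueError(
            f"target {target} unattainable: achievable bracket is "
            f"[{p_lo:.3f}, {p_hi:.3f}] for w_align in [{lo}, {hi}]"
        )
    best_w, best_p = (lo, p_lo) if abs(p_lo - target) < abs(p_hi - target) else (hi, p_hi)
    for _ in range(max_iter):
        if abs(best_p - target) <= tol:
            break
        mid = (lo + hi) / 2.0
        p_mid = _eval(mid)
        if abs(p_mid - target) < abs(best_p - target):
            best_w, best_p = mid, p_mid
        if p_mid < target:
            lo = mid
        else:
            hi = mid
    if abs(best_p - target) > tol:
        raise ValueError(
            f"calibration failed: best polarization {best_p:.3f} at w_align={best_w:.3f} "
            f"for target {target}"
        )
    return replace(template, w_align=best_w)
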