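"""Individual- and group-level trajectory parameters.

Six individual parameters — swimming speed, distance to the stimulus,
bearing to the stimulus, proportion of time on the convex-hull edge,
distance to the group centroid, and visual occlusion — and five group
parameters — convex hull area, bearing of the group heading to the
stimulus, distance of the group centroid to the stimulus, centroid speed,
and polarization — summarized over a short pre-stimulus window (13 frames,
0.5 s at 25 fps) by their median (a proportion of frames for the hull-edge
parameter).  Individual parameters are also expressed relative to the
group mean so that "who responds first" is modelled as a within-group
contest.

Headings are derived from smoothed displacement (centre-of-mass tracking
carries no body axis); frames where a fish moves slower than ``speed_floor``
have no defined direction and are excluded from direction-based statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .io import TrajectorySet

__all__ = [
    "HeadingField",
    "headings_from_displacement",
    "polarization",
    "bearing_to_target",
    "group_metrics_frame",
    "window_summary",
    "relativize_group",
    "bearing_dispersion",
    "nn_heading_difference",
    "hull_vertices_mask",
]

SPEED_FLOOR_MM_PER_FRAME = 0.3


@dataclass
class HeadingField:
    """Unit headings (n_fish, n_frames, 2) with validity and per-frame speed.

    ``headings`` is NaN where invalid; ``speed`` is the displacement per
    frame (mm/frame) by central difference, NaN at gaps and endpoints.
    """

    headings: np.ndarray
    speed: np.ndarray
    valid: np.ndarray


def headings_from_displacement(
    traj: TrajectorySet, speed_floor: float = SPEED_FLOOR_MM_PER_FRAME
) -> HeadingField:
    """Heading at frame t = unit central-difference displacement.

    Uses (p[t+1] - p[t-1]) / 2; one-sided differences at run endpoints.
    Frames moving slower than ``speed_floor`` (mm/frame) are invalid.
    """
    pos = traj.positions
    vel = np.full_like(pos, np.nan)
    vel[:, 1:-1] = (pos[:, 2:] - pos[:, :-2]) / 2.0
    vel[:, 0] = pos[:, 1] - pos[:, 0]
    vel[:, -1] = pos[:, -1] - pos[:, -2]
    # one-sided at interior gap edges
    interior_nan = np.isnan(vel).any(axis=2)
    tracked = traj.tracked()
    fwd = np.full_like(pos, np.nan)
    fwd[:, :-1] = pos[:, 1:] - pos[:, :-1]
    bwd = np.full_like(pos, np.nan)
    bwd[:, 1:] = pos[:, 1:] - pos[:, :-1]
    use_fwd = interior_nan & tracked & ~np.isnan(fwd).any(axis=2)
    vel[use_fwd] = fwd[use_fwd]
    still_nan = np.isnan(vel).any(axis=2)
    use_bwd = still_nan & tracked & ~np.isnan(bwd).any(axis=2)
    vel[use_bwd] = bwd[use_bwd]

    speed = np.linalg.norm(vel, axis=2)
    valid = np.isfinite(speed) & (speed >= speed_floor)
    headings = np.full_like(pos, np.nan)
    headings[valid] = vel[valid] / speed[valid, None]
    return HeadingField(headings=headings, speed=speed, valid=valid)


def polarization(headings: np.ndarray) -> float:
    """Order parameter |mean of unit headings| in [0, 1].

    1 when all individuals share a heading, 0 when directions cancel.
    NaN rows (invalid headings) are dropped; fewer than two valid headings
    leave the quantity undefined (NaN).
    """
    h = np.asarray(headings, dtype=float).reshape(-1, 2)
    h = h[~np.isnan(h).any(axis=1)]
    if h.shape[0] < 2:
        return float("nan")
    return float(np.linalg.norm(h.mean(axis=0)))


def bearing_to_target(
    position: np.ndarray, heading: np.ndarray, target: np.ndarray
) -> float:
    """Unsigned angle (degrees, [0, 180]) between a heading and the line to a target."""
    position = np.asarray(position, dtype=float)
    target = np.asarray(target, dtype=float)
    to_t = target - position
    d = np.linalg.norm(to_t)
    if d == 0:
        raise ValueError("target coincides with position; bearing undefined")
    h = np.asarray(heading, dtype=float)
    hn = np.linalg.norm(h)
    if not np.isfinite(hn) or hn == 0:
        return float("nan")
    cosang = np.clip(np.dot(h / hn, to_t / d), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _bearings_frame(
    pos: np.ndarray, headings: np.ndarray, target: np.ndarray
) -> np.ndarray:
    """Vectorized unsigned bearings for many fish at one frame (NaN-safe)."""
    to_t = np.asarray(target, dtype=float) - pos
    d = np.linalg.norm(to_t, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("...i,...i->...", headings, to_t) / np.maximum(d, 1e-12)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def hull_vertices_mask(points: np.ndarray) -> np.ndarray:
    """Boolean mask of which points are vertices of their convex hull.

    Degenerate (collinear) sets have zero hull area; every point is then
    flagged as on the edge.
    """
    n = points.shape[0]
    if n <= 3:
        return np.ones(n, dtype=bool)
    try:
        hull = ConvexHull(points)
    except QhullError:
        return np.ones(n, dtype=bool)
    mask = np.zeros(n, dtype=bool)
    mask[hull.vertices] = True
    return mask


def convex_hull_area(points: np.ndarray) -> float:
    """Area of the convex hull of 2-D points (0 for degenerate sets)."""
    if points.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(points).volume)  # "volume" is area in 2-D
    except QhullError:
        return 0.0


def group_metrics_frame(
    traj: TrajectorySet,
    field: HeadingField,
    stimulus: np.ndarray,
    t: int,
) -> dict:
    """Single-frame group summary at frame index position ``t`` (frame number).

    Returns hull area (mm^2), centroid, centroid speed (mm/frame, central
    difference of the centroid track), group bearing to the stimulus (from
    the direction of the summed unit headings), centroid distance to the
    stimulus, polarization, and the per-fish hull-edge flags.  Raises
    ``KeyError`` for a frame outside the range and ``ValueError`` if any
    fish is untracked at ``t``.
    """
    i = traj.frame_index(t)
    pts = traj.positions[:, i]
    if np.isnan(pts).any():
        raise ValueError(f"frame {t}: not all fish tracked")
    centroid = pts.mean(axis=0)
    # centroid speed via central difference where neighbours exist
    if 0 < i < traj.n_frames - 1 and not np.isnan(traj.positions[:, [i - 1, i + 1]]).any():
        cprev = traj.positions[:, i - 1].mean(axis=0)
        cnext = traj.positions[:, i + 1].mean(axis=0)
        centroid_speed = float(np.linalg.norm(cnext - cprev) / 2.0)
    else:
        centroid_speed = float("nan")
    h = field.headings[:, i]
    pol = polarization(h)
    hsum = np.nansum(h, axis=0)
    if np.linalg.norm(hsum) > 0 and field.valid[:, i].sum() >= 2:
        group_bearing = bearing_to_target(centroid, hsum, stimulus)
    else:
        group_bearing = float("nan")
    edge = hull_vertices_mask(pts)
    return {
        "hull_area": convex_hull_area(pts),
        "centroid": centroid,
        "centroid_speed": centroid_speed,
        "centroid_dist_stimulus": float(np.linalg.norm(np.asarray(stimulus) - centroid)),
        "group_bearing_stimulus": group_bearing,
        "polarization": pol,
        "on_hull_edge": edge,
    }


def window_summary(series: np.ndarray, stat: str = "median") -> float:
    """Summary of a per-frame series over a pre-stimulus window.

    The median is the default: it damps tracking outliers and suits the
    skewed distributions these parameters have.  Any NaN in the window
    (tracking gap, undefined heading) leaves the summary undefined.
    """
    x = np.asarray(series, dtype=float)
    if np.isnan(x).any() or x.size == 0:
        return float("nan")
    if stat == "median":
        return float(np.median(x))
    if stat == "mean":
        return float(np.mean(x))
    raise ValueError(f"unknown stat {stat!r}")


def relativize_group(values: np.ndarray) -> np.ndarray:
    """Per-fish values divided by their group mean (relative measures).

    By construction the relative values of a group average to 1.  A zero
    (or undefined) group mean leaves the result undefined.
    """
    v = np.asarray(values, dtype=float)
    m = np.mean(v)
    if not np.isfinite(m) or m == 0:
        return np.full_like(v, np.nan)
    return v / m


def bearing_dispersion(bearings: np.ndarray) -> tuple[float, float]:
    """(sample SD, minimum) of the group's unsigned bearings to the stimulus.

    Low polarization spreads individual bearings over [0, 180], raising the
    SD and (with eight fish) typically dropping the minimum — the geometry
    by which disorder buys the group earlier lines of sight.
    """
    b = np.asarray(bearings, dtype=float)
    b = b[np.isfinite(b)]
    if b.size < 2:
        return float("nan"), float(b[0]) if b.size else float("nan")
    return float(np.std(b, ddof=1)), float(np.min(b))


def nn_heading_difference(
    traj: TrajectorySet, field: HeadingField, t: int
) -> np.ndarray:
    """Unsigned heading difference (degrees) of each fish to its nearest neighbour.

    Nearest by Euclidean distance at frame ``t``; ties resolved to the
    lower fish index.  NaN where either heading is invalid.
    """
    i = traj.frame_index(t)
    pts = traj.positions[:, i]
    h = field.headings[:, i]
    n = traj.n_fish
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    d[np.isnan(d)] = np.inf
    out = np.full(n, np.nan)
    for k in range(n):
        j = int(np.argmin(d[k]))  # argmin takes the first (lowest id) on ties
        if not np.isfinite(d[k, j]):
            continue
        if np.isnan(h[k]).any() or np.isnan(h[j]).any():
            continue
        cosang = np.clip(np.dot(h[k], h[j]), -1.0, 1.0)
        out[k] = np.degrees(np.arccos(cosang))
    return out


def window_metrics(
    traj: TrajectorySet,
    field: HeadingField,
    stimulus: np.ndarray,
    onset_frame: int,
    window_frames: int = 13,
    occlusion: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict] | tuple[None, None]:
    """All individual and group parameters over the pre-stimulus window.

    The window is the ``window_frames`` frames ending the frame before
    ``onset_frame``.  Returns (per-fish DataFrame, group dict), or
    (None, None) if the window has tracking gaps.

    ``occlusion`` may supply the per-fish visual-occlusion index for the
    window (computed by :mod:`shoalsight.vision`); it is relativized along
    with the other parameters.
    """
    start = onset_frame - window_frames
    try:
        sl = traj.window_slice(start, window_frames)
    except KeyError:
        return None, None
    if sl.stop > traj.n_frames or not traj.tracked()[:, sl].all():
        return None, None
    stimulus = np.asarray(stimulus, dtype=float)

    pos = traj.positions[:, sl]
    h = field.headings[:, sl]
    speed = field.speed[:, sl]
    n = traj.n_fish

    centroids = pos.mean(axis=0)
    dist_stim = np.linalg.norm(pos - stimulus, axis=2)
    dist_centroid = np.linalg.norm(pos - centroids[None], axis=2)
    bearings = _bearings_frame(pos, h, stimulus)

    per_frame_group = []
    edge_flags = np.zeros((n, window_frames), dtype=bool)
    for k, fr in enumerate(range(start, start + window_frames)):
        g = group_metrics_frame(traj, field, stimulus, fr)
        per_frame_group.append(g)
        edge_flags[:, k] = g["on_hull_edge"]

    indiv = pd.DataFrame(
        {
            "fish_id": traj.fish_ids,
            "speed": [window_summary(speed[i]) for i in range(n)],
            "dist_stimulus": [window_summary(dist_stim[i]) for i in range(n)],
            "bearing_stimulus": [window_summary(bearings[i]) for i in range(n)],
            "prop_hull_edge": edge_flags.mean(axis=1),
            "dist_centroid": [window_summary(dist_centroid[i]) for i in range(n)],
            "body_length_mm": traj.body_length_mm,
        }
    )
    if occlusion is not None:
        indiv["occlusion"] = np.asarray(occlusion, dtype=float)
    rel_cols = ["speed", "dist_stimulus", "bearing_stimulus", "prop_hull_edge",
                "dist_centroid", "body_length_mm"] + (
        ["occlusion"] if occlusion is not None else [])
    for col in rel_cols:
        indiv[f"rel_{col}"] = relativize_group(indiv[col].to_numpy())

    med_bearings = indiv["bearing_stimulus"].to_numpy()
    b_sd, b_min = bearing_dispersion(med_bearings)
    group = {
        "hull_area": window_summary([g["hull_area"] for g in per_frame_group]),
        "group_bearing_stimulus": window_summary(
            [g["group_bearing_stimulus"] for g in per_frame_group]
        ),
        "centroid_dist_stimulus": window_summary(
            [g["centroid_dist_stimulus"] for g in per_frame_group]
        ),
        "centroid_speed": window_summary(
            [g["centroid_speed"] for g in per_frame_group]
        ),
        "polarization": window_summary(
            [g["polarization"] for g in per_frame_group]
        ),
        "bearing_sd": b_sd,
        "min_bearing": b_min,
    }
    return indiv, group
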