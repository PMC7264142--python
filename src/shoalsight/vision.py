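"""Ray-cast 2-D visual fields with neighbour-body occlusion.

Each fish is given a single cyclopean eye slightly ahead of its tracked
centre-of-mass, a frontal *binocular* sector (where the two monocular
fields overlap, the region relevant for prey detection) and a wide *full*
field that adds the monocular flanks.  Rays fanned across the chosen
sector stop at the first of: a neighbour's body (an ellipse aligned with
its heading), the arena wall, or a maximum range.  The polygon of ray
endpoints approximates the visible region; the fraction of rays stopped
by neighbours is the visual-occlusion index.

Field angles are stand-ins (the true stickleback angles are not pinned
down here): binocular half-angle 15 deg and a 300 deg total field by
default, both configurable — downstream conclusions should be checked
across a range of plausible angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .arena import ArenaGeometry

__all__ = [
    "VisionConfig",
    "BodyModel",
    "VisibilityResult",
    "cast_field",
    "stimulus_visible_any",
    "collective_coverage",
    "occlusion_index",
    "body_models",
    "segment_blocked",
]


@dataclass(frozen=True)
class VisionConfig:
    binocular_half_angle_deg: float = 15.0
    full_field_deg: float = 300.0
    n_rays: int = 720  # rays per 360 deg; sectors get a proportional share
    max_range_mm: float | None = None  # None -> arena diagonal
    eye_offset_bl: float = 0.4  # eye ahead of centre-of-mass, in body lengths
    body_aspect: float = 0.2  # occluder ellipse minor/major axis ratio

    def __post_init__(self) -> None:
        if not (0 < self.binocular_half_angle_deg < 90):
            raise ValueError("binocular half-angle must be in (0, 90) degrees")
        if not (0 < self.full_field_deg <= 360):
            raise ValueError("full field must be in (0, 360] degrees")
        if self.n_rays < 90:
            raise ValueError("need at least 90 rays per 360 degrees")

    def field_half_angle(self, field: str) -> float:
        if field == "binocular":
            return math.radians(self.binocular_half_angle_deg)
        if field == "full":
            return math.radians(self.full_field_deg / 2.0)
        raise ValueError(f"unknown field {field!r}")


@dataclass(frozen=True)
class BodyModel:
    """Elliptical occluder: centre at the fish, major axis along its heading."""

    fish_id: int
    centre: tuple[float, float]
    heading_rad: float
    semi_major_mm: float
    semi_minor_mm: float


@dataclass
class VisibilityResult:
    fish_id: int
    visible_polygon: np.ndarray  # (m, 2) vertex loop
    coverage_fraction: float
    blocked_ray_fraction: float
    stimulus_visible: bool | None


def body_models(
    positions: np.ndarray,
    heading_angles: np.ndarray,
    body_lengths: np.ndarray,
    config: VisionConfig,
    fish_ids: list[int] | None = None,
) -> list[BodyModel]:
    """Occluder ellipses for a set of fish (invalid headings -> axis-aligned)."""
    n = positions.shape[0]
    ids = fish_ids if fish_ids is not None else list(range(n))
    out = []
    for i in range(n):
        ang = heading_angles[i] if np.isfinite(heading_angles[i]) else 0.0
        out.append(
            BodyModel(
                fish_id=ids[i],
                centre=(float(positions[i, 0]), float(positions[i, 1])),
                heading_rad=float(ang),
                semi_major_mm=float(body_lengths[i] / 2.0),
                semi_minor_mm=float(config.body_aspect * body_lengths[i] / 2.0),
            )
        )
    return out


def _ray_ellipse_t(origin: np.ndarray, dirs: np.ndarray, body: BodyModel) -> np.ndarray:
    """Smallest positive ray parameter hitting an ellipse; inf if missed.

    The ray is mapped into the ellipse frame (rotate by -heading, scale the
    axes to a unit circle) where the intersection is a quadratic.
    """
    c, s = math.cos(body.heading_rad), math.sin(body.heading_rad)
    R = np.array([[c, s], [-s, c]])  # world -> body frame
    scale = np.array([1.0 / body.semi_major_mm, 1.0 / body.semi_minor_mm])
    o = (R @ (origin - np.asarray(body.centre))) * scale
    d = (dirs @ R.T) * scale
    a = np.einsum("ij,ij->i", d, d)
    b = d @ o
    cc = float(o @ o) - 1.0
    disc = b**2 - a * cc
    t = np.full(dirs.shape[0], np.inf)
    ok = disc >= 0
    sq = np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-b - sq) / a
        t2 = (-b + sq) / a
    # smallest positive root; origin inside the ellipse sees t2
    cand = np.where(t1 > 1e-9, t1, np.where(t2 > 1e-9, t2, np.inf))
    t[ok] = cand[ok]
    t[~ok] = np.inf
    return t


def _eye_point(position: np.ndarray, heading_angle: float, body_length: float,
               config: VisionConfig, arena: ArenaGeometry | None = None) -> np.ndarray:
    u = np.array([math.cos(heading_angle), math.sin(heading_angle)])
    eye = np.asarray(position, dtype=float) + config.eye_offset_bl * body_length * u
    if arena is not None:
        # a fish nosed against the wall can put the eye outside the arena;
        # pull it back just inside so wall ray casting stays well defined
        sd = float(arena.signed_distance(eye))
        if sd > -1.0:
            eye = eye + (sd + 1.0) * arena.inward_normal_at(eye)
    return eye


def cast_field(
    position: np.ndarray,
    heading_angle: float,
    body_length: float,
    others: list[BodyModel],
    arena: ArenaGeometry,
    config: VisionConfig,
    field: str = "binocular",
    stimulus: np.ndarray | None = None,
    fish_id: int = -1,
) -> VisibilityResult:
    """Ray-cast one fish's visible region for the chosen field.

    Rays fan symmetrically about the heading across the field; each stops
    at the nearest of (neighbour body, wall, max range).  The visible
    region is the polygon through the eye point (dropped for a full 360
    deg field) and the ray endpoints.
    """
    if not np.isfinite(heading_angle):
        raise ValueError("cannot cast a visual field from an invalid heading")
    half = config.field_half_angle(field)
    n_rays = max(8, int(round(config.n_rays * (2 * half) / (2 * math.pi))))
    eye = _eye_point(position, heading_angle, body_length, config, arena)
    max_range = config.max_range_mm if config.max_range_mm is not None else arena.diagonal_mm

    rel = np.linspace(-half, half, n_rays)
    ang = heading_angle + rel
    dirs = np.stack([np.cos(ang), np.sin(ang)], axis=1)

    t_wall = arena.ray_wall_distance(eye, dirs)
    t_stop = np.minimum(t_wall, max_range)
    t_body = np.full(n_rays, np.inf)
    for b in others:
        if b.fish_id == fish_id:
            continue
        t_body = np.minimum(t_body, _ray_ellipse_t(eye, dirs, b))
    blocked = t_body < t_stop
    t_final = np.where(blocked, t_body, t_stop)
    endpoints = eye + t_final[:, None] * dirs

    full_circle = 2 * half >= 2 * math.pi - 1e-9
    verts = endpoints if full_circle else np.vstack([eye, endpoints])
    poly = Polygon(verts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    coverage = poly.area / arena.area_mm2

    stim_vis: bool | None = None
    if stimulus is not None:
        stim_vis = _point_visible(eye, heading_angle, half, np.asarray(stimulus),
                                  others, max_range, fish_id)
    return VisibilityResult(
        fish_id=fish_id,
        visible_polygon=np.asarray(poly.exterior.coords) if poly.area > 0 else verts,
        coverage_fraction=float(coverage),
        blocked_ray_fraction=float(np.mean(blocked)),
        stimulus_visible=stim_vis,
    )


def _point_visible(
    eye: np.ndarray,
    heading_angle: float,
    half: float,
    point: np.ndarray,
    others: list[BodyModel],
    max_range: float,
    fish_id: int,
) -> bool:
    """Is a point inside the angular field and unoccluded along the sight line?

    The arena is convex, so the wall can never block a line between two
    interior points; only neighbour bodies and range matter.
    """
    rel = point - eye
    dist = float(np.linalg.norm(rel))
    if dist == 0:
        return True
    if dist > max_range:
        return False
    ang = math.atan2(rel[1], rel[0])
    dang = (ang - heading_angle + math.pi) % (2 * math.pi) - math.pi
    if abs(dang) > half:
        return False
    return not segment_blocked(eye, point, others, fish_id)


def segment_blocked(
    p0: np.ndarray, p1: np.ndarray, others: list[BodyModel], fish_id: int = -1
) -> bool:
    """True if any neighbour body intersects the open segment p0 -> p1."""
    d = np.asarray(p1, dtype=float) - np.asarray(p0, dtype=float)
    dist = float(np.linalg.norm(d))
    if dist == 0:
        return False
    u = (d / dist)[None, :]
    for b in others:
        if b.fish_id == fish_id:
            continue
        t = _ray_ellipse_t(np.asarray(p0, dtype=float), u, b)[0]
        if t < dist:
            return True
    return False


def stimulus_visible_any(
    positions: np.ndarray,
    heading_angles: np.ndarray,
    body_lengths: np.ndarray,
    stimulus: np.ndarray,
    arena: ArenaGeometry,
    config: VisionConfig,
    field: str = "binocular",
    fish_ids: list[int] | None = None,
) -> tuple[bool, set]:
    """Does any group member currently see the stimulus, and which ones?"""
    ids = fish_ids if fish_ids is not None else list(range(positions.shape[0]))
    bodies = body_models(positions, heading_angles, body_lengths, config, ids)
    half = config.field_half_angle(field)
    max_range = config.max_range_mm if config.max_range_mm is not None else arena.diagonal_mm
    seers = set()
    for i, fid in enumerate(ids):
        if not np.isfinite(heading_angles[i]):
            continue
        eye = _eye_point(positions[i], heading_angles[i], body_lengths[i], config, arena)
        if _point_visible(eye, heading_angles[i], half, np.asarray(stimulus),
                          bodies, max_range, fid):
            seers.add(fid)
    return (len(seers) > 0, seers)


def collective_coverage(
    positions: np.ndarray,
    heading_angles: np.ndarray,
    body_lengths: np.ndarray,
    arena: ArenaGeometry,
    config: VisionConfig,
    field: str = "binocular",
) -> float:
    """Fraction of the arena covered by the union of the group's visible regions."""
    ids = list(range(positions.shape[0]))
    bodies = body_models(positions, heading_angles, body_lengths, config, ids)
    polys = []
    for i in ids:
        if not np.isfinite(heading_angles[i]):
            continue
        res = cast_field(positions[i], heading_angles[i], body_lengths[i], bodies,
                         arena, config, field=field, fish_id=i)
        p = Polygon(res.visible_polygon)
        if not p.is_valid:
            p = p.buffer(0)
        if p.area > 0:
            polys.append(p)
    if not polys:
        return 0.0
    return float(unary_union(polys).area / arena.area_mm2)


def occlusion_index(
    position: np.ndarray,
    heading_angle: float,
    body_length: float,
    others: list[BodyModel],
    arena: ArenaGeometry,
    config: VisionConfig,
    fish_id: int = -1,
) -> float:
    """Fraction of the full visual field intercepted by neighbour bodies."""
    res = cast_field(position, heading_angle, body_length, others, arena, config,
                     field="full", fish_id=fish_id)
    return res.blocked_ray_fraction
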