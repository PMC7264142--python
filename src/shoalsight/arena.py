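"""Arena geometry for an oval (stadium or ellipse) test tank.

The experimental tank is an oval of 133.5 x 72 cm with stimulus ports set
into the wall.  The exact curve of a real "oval" PVC tank is unknown, so two
idealisations are offered:

* ``stadium`` (default): a rectangle capped by two semicircles — the shape a
  flat sheet bent around two half-cylinders takes naturally;
* ``ellipse``: a true ellipse with the same bounding box.

All geometry is 2-D, in millimetres, Cartesian, origin at the arena centre,
y up.  Both shapes are convex, which the ray-casting module relies on (a
sight line between two interior points can never leave the arena).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArenaGeometry",
    "StimulusPort",
    "UnitSystem",
    "default_arena",
    "point_in_arena",
]


@dataclass(frozen=True)
class StimulusPort:
    """A hole in the arena wall through which the stimulus appears."""

    id: int
    position: tuple[float, float]
    inward_normal: tuple[float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.inward_normal, dtype=float)
        norm = float(np.hypot(*n))
        if not math.isclose(norm, 1.0, abs_tol=1e-6):
            object.__setattr__(self, "inward_normal", tuple(n / norm))


@dataclass(frozen=True)
class UnitSystem:
    """Conversion between raw tracker units (pixels, frames) and mm / s."""

    fps: float = 25.0
    px_per_mm: float = 2.7

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.px_per_mm <= 0:
            raise ValueError("fps and px_per_mm must be positive")

    def px_to_mm(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(x, dtype=float) / self.px_per_mm

    def mm_to_px(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(x, dtype=float) * self.px_per_mm

    def frames_to_seconds(self, f: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(f, dtype=float) / self.fps


@dataclass(frozen=True)
class ArenaGeometry:
    """Oval arena: long axis ``length_mm``, short axis ``width_mm``.

    ``shape`` selects the boundary curve: ``"stadium"`` (rectangle with
    semicircular end caps) or ``"ellipse"``.
    """

    length_mm: float = 1335.0
    width_mm: float = 720.0
    shape: str = "stadium"
    ports: tuple[StimulusPort, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.length_mm > self.width_mm > 0):
            raise ValueError("require length_mm > width_mm > 0")
        if self.shape not in ("stadium", "ellipse"):
            raise ValueError(f"unknown arena shape {self.shape!r}")
        if self.ports and not (1 <= len(self.ports) <= 8):
            raise ValueError("between 1 and 8 ports")
        for p in self.ports:
            d = abs(self.signed_distance(np.asarray(p.position)))
            if d > 1.0:
                raise ValueError(
                    f"port {p.id} lies {d:.2f} mm from the boundary (tolerance 1 mm)"
                )

    # stadium parameters: core segment half-length a, cap radius r
    @property
    def _a(self) -> float:
        return (self.length_mm - self.width_mm) / 2.0

    @property
    def _r(self) -> float:
        return self.width_mm / 2.0

    @property
    def area_mm2(self) -> float:
        if self.shape == "stadium":
            return 2 * self._a * self.width_mm + math.pi * self._r**2
        return math.pi * (self.length_mm / 2) * (self.width_mm / 2)

    @property
    def diagonal_mm(self) -> float:
        return math.hypot(self.length_mm, self.width_mm)

    def signed_distance(self, p: np.ndarray) -> np.ndarray:
        """Signed distance to the boundary: negative inside, positive outside."""
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        if self.shape == "stadium":
            # distance to the core segment, minus cap radius
            cx = np.clip(x, -self._a, self._a)
            return np.hypot(x - cx, y) - self._r
        # ellipse: approximate signed distance via the scaled radial residual.
        # Exact enough near the boundary for port validation and wall avoidance.
        ax, by = self.length_mm / 2, self.width_mm / 2
        rho = np.hypot(x / ax, y / by)
        grad = np.hypot(x / ax**2, y / by**2)
        return np.where(grad > 0, (rho**2 - 1) / (2 * np.maximum(grad, 1e-12)), -by)

    def contains(self, p: np.ndarray) -> np.ndarray:
        """True for points strictly inside the boundary."""
        return self.signed_distance(p) < 0

    def inward_normal_at(self, p: np.ndarray) -> np.ndarray:
        """Unit normal pointing into the arena, for a point at/near the wall."""
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        if self.shape == "stadium":
            cx = np.clip(x, -self._a, self._a)
            out = np.stack([x - cx, np.asarray(y, dtype=float)], axis=-1)
        else:
            ax, by = self.length_mm / 2, self.width_mm / 2
            out = np.stack([x / ax**2, y / by**2], axis=-1)
        n = np.linalg.norm(out, axis=-1, keepdims=True)
        return -out / np.maximum(n, 1e-12)

    def boundary_polygon(self, n_vertices: int = 256) -> np.ndarray:
        """Counter-clockwise polygonal approximation of the wall, (n, 2)."""
        if self.shape == "ellipse":
            t = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
            return np.stack(
                [self.length_mm / 2 * np.cos(t), self.width_mm / 2 * np.sin(t)], axis=1
            )
        a, r = self._a, self._r
        n_cap = max(8, n_vertices // 2) // 2 * 2
        t_right = np.linspace(-math.pi / 2, math.pi / 2, n_cap)
        t_left = np.linspace(math.pi / 2, 3 * math.pi / 2, n_cap)
        right = np.stack([a + r * np.cos(t_right), r * np.sin(t_right)], axis=1)
        left = np.stack([-a + r * np.cos(t_left), r * np.sin(t_left)], axis=1)
        return np.concatenate([right, left], axis=0)

    def boundary_point_at_x(self, x: float, side: int = 1) -> np.ndarray:
        """Wall point at a given x on the upper (side=+1) or lower (-1) wall."""
        if abs(x) > self.length_mm / 2:
            raise ValueError("x beyond the arena")
        if self.shape == "ellipse":
            y = self.width_mm / 2 * math.sqrt(max(0.0, 1 - (2 * x / self.length_mm) ** 2))
        elif abs(x) <= self._a:
            y = self._r
        else:
            y = math.sqrt(max(0.0, self._r**2 - (abs(x) - self._a) ** 2))
        return np.array([x, side * y])

    def ray_wall_distance(self, origin: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Distance from an interior ``origin`` to the wall along each unit ray.

        ``directions`` is (n, 2); returns (n,).  Solved analytically: lateral
        wall lines plus end-cap circles for the stadium, a scaled circle for
        the ellipse.
        """
        o = np.asarray(origin, dtype=float)
        d = np.asarray(directions, dtype=float)
        if self.shape == "ellipse":
            s = np.array([2.0 / self.length_mm, 2.0 / self.width_mm])
            os_, ds = o * s, d * s
            a2 = np.einsum("ij,ij->i", ds, ds)
            b = np.einsum("j,ij->i", os_, ds)
            c = float(os_ @ os_) - 1.0
            disc = np.maximum(b**2 - a2 * c, 0.0)
            return (-b + np.sqrt(disc)) / a2

        a, r = self._a, self._r
        t_best = np.full(d.shape[0], np.inf)
        # lateral walls y = +-r, valid while |x| <= a
        for yw in (r, -r):
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (yw - o[1]) / d[:, 1]
            x_hit = o[0] + t * d[:, 0]
            ok = (t > 1e-9) & (np.abs(x_hit) <= a) & np.isfinite(t)
            t_best = np.where(ok & (t < t_best), t, t_best)
        # end caps: circles of radius r at (+-a, 0), valid on the outer halves
        for cx, sign in ((a, 1.0), (-a, -1.0)):
            oc = o - np.array([cx, 0.0])
            b = d @ oc
            c = float(oc @ oc) - r**2
            disc = b**2 - c
            ok_d = disc >= 0
            sq = np.sqrt(np.maximum(disc, 0.0))
            for t in (-b - sq, -b + sq):
                x_hit = o[0] + t * d[:, 0]
                ok = ok_d & (t > 1e-9) & (sign * (x_hit - cx) >= -1e-9)
                t_best = np.where(ok & (t < t_best), t, t_best)
        return t_best


def default_arena(shape: str = "stadium", port_frac: float = 0.25) -> ArenaGeometry:
    """The 133.5 x 72 cm tank with four wall ports.

    Ports are placed two per long side at ``+-port_frac`` of the long axis —
    a stand-in layout; real port coordinates should come from configuration.
    """
    geom = ArenaGeometry(shape=shape)
    ports = []
    pid = 0
    for side in (1, -1):
        for fx in (-port_frac, port_frac):
            pos = geom.boundary_point_at_x(fx * geom.length_mm, side=side)
            normal = geom.inward_normal_at(pos)
            pid += 1
            ports.append(StimulusPort(pid, tuple(pos), tuple(normal)))
    return ArenaGeometry(shape=shape, ports=tuple(ports))


def point_in_arena(arena: ArenaGeometry, p: np.ndarray) -> bool | np.ndarray:
    """True iff ``p`` is strictly inside the arena boundary."""
    res = arena.contains(p)
    return bool(res) if np.ndim(res) == 0 else res
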