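"""YAML configuration for arena geometry, units and response criteria.

Example::

    arena:
      length_mm: 1335
      width_mm: 720
      shape: stadium
      ports:            # optional; default layout used when omitted
        - {id: 1, x: -333.75, y: 359.04}
        - {id: 2, x: 333.75, y: 359.04}
    units:
      fps: 25
      px_per_mm: 2.7
    response_criteria:
      bearing_threshold_deg: 30
      speed_factor: 1.5
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .arena import ArenaGeometry, StimulusPort, UnitSystem, default_arena
from .events import ResponseCriteria

__all__ = ["load_config", "arena_from_dict"]


def arena_from_dict(spec: dict) -> ArenaGeometry:
    """Build an arena from a config mapping; ports get inward normals
    computed from the geometry."""
    geom = ArenaGeometry(
        length_mm=float(spec.get("length_mm", 1335.0)),
        width_mm=float(spec.get("width_mm", 720.0)),
        shape=spec.get("shape", "stadium"),
    )
    if "ports" not in spec:
        return default_arena(shape=geom.shape)
    ports = tuple(
        StimulusPort(
            int(p["id"]),
            (float(p["x"]), float(p["y"])),
            tuple(geom.inward_normal_at(np.array([p["x"], p["y"]], dtype=float))),
        )
        for p in spec["ports"]
    )
    return ArenaGeometry(geom.length_mm, geom.width_mm, geom.shape, ports)


def load_config(path: str | Path) -> dict:
    """Read a YAML config into typed objects.

    Returns ``{"arena": ArenaGeometry, "units": UnitSystem,
    "response_criteria": ResponseCriteria}``; missing sections fall back
    to the package defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return {
        "arena": arena_from_dict(raw.get("arena", {})),
        "units": UnitSystem(**raw.get("units", {})),
        "response_criteria": ResponseCriteria(**raw.get("response_criteria", {})),
    }
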