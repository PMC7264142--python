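"""Trajectory ingestion, unit conversion and Savitzky-Golay smoothing.

Input is an idTracker-style long table (``frame,id,x,y[,prob]``), one row per
individual per frame, in pixel image coordinates.  On read, positions are
converted to millimetres and to Cartesian axes (y up, origin at the arena
centre); missing frames stay as NaN and are never interpolated — downstream
windows that touch a gap are dropped rather than filled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .arena import ArenaGeometry, UnitSystem

log = logging.getLogger("shoalsight")

__all__ = ["TrajectorySet", "read_trajectories", "write_trajectories", "smooth_savgol"]

MEAN_BODY_LENGTH_MM = 27.0  # cohort mean standard body length


@dataclass
class TrajectorySet:
    """Per-frame positions (mm, Cartesian) for all members of one group.

    ``positions`` has shape (n_fish, n_frames, 2); untracked samples are NaN.
    ``frames`` is the strictly increasing frame index (no holes: a missing
    frame is a NaN row, not an absent one).
    """

    group_id: str
    fish_ids: list[int]
    frames: np.ndarray
    positions: np.ndarray
    body_length_mm: np.ndarray | None = None
    source_units: UnitSystem = field(default_factory=UnitSystem)
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        n_fish = len(self.fish_ids)
        if n_fish < 2:
            raise ValueError("a trajectory set needs at least two individuals")
        if self.positions.shape != (n_fish, self.frames.size, 2):
            raise ValueError("positions must have shape (n_fish, n_frames, 2)")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame index must be strictly increasing")
        if self.body_length_mm is None:
            self.body_length_mm = np.full(n_fish, MEAN_BODY_LENGTH_MM)
        else:
            self.body_length_mm = np.asarray(self.body_length_mm, dtype=float)

    @property
    def n_fish(self) -> int:
        return len(self.fish_ids)

    @property
    def n_frames(self) -> int:
        return self.frames.size

    def tracked(self) -> np.ndarray:
        """(n_fish, n_frames) mask of frames with a valid position."""
        return ~np.isnan(self.positions).any(axis=2)

    def frame_index(self, frame: int) -> int:
        idx = int(np.searchsorted(self.frames, frame))
        if idx >= self.frames.size or self.frames[idx] != frame:
            raise KeyError(f"frame {frame} not in trajectory range")
        return idx

    def window_slice(self, start_frame: int, n: int) -> slice:
        i = self.frame_index(start_frame)
        return slice(i, i + n)


def read_trajectories(
    path,
    units: UnitSystem | None = None,
    arena: ArenaGeometry | None = None,
    group_id: str = "group",
    body_length_mm: dict[int, float] | None = None,
    coords: str = "image_px",
    image_size: tuple[float, float] | None = None,
    boundary_tol_mm: float = 20.0,
) -> TrajectorySet:
    """Read an idTracker-like CSV into a :class:`TrajectorySet`.

    Parameters
    ----------
    coords
        ``"image_px"`` (default): pixel coordinates, y down, origin at the
        image corner — converted to mm and flipped to y-up about the arena
        centre (taken as the image centre unless ``image_size`` is given).
        ``"cartesian_mm"``: already in this package's convention; passed
        through unchanged.
    """
    units = units or UnitSystem()
    df = pd.read_csv(path)
    required = {"frame", "id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory table needs columns {sorted(required)}")
    if df.duplicated(subset=["frame", "id"]).any():
        raise ValueError("duplicate (fish, frame) rows in trajectory table")

    fish_ids = sorted(df["id"].unique())
    f0, f1 = int(df["frame"].min()), int(df["frame"].max())
    frames = np.arange(f0, f1 + 1)
    pos = np.full((len(fish_ids), frames.size, 2), np.nan)
    fish_pos = {fid: k for k, fid in enumerate(fish_ids)}
    rows_f = df["frame"].to_numpy(dtype=int) - f0
    rows_i = df["id"].map(fish_pos).to_numpy(dtype=int)
    pos[rows_i, rows_f, 0] = df["x"].to_numpy(dtype=float)
    pos[rows_i, rows_f, 1] = df["y"].to_numpy(dtype=float)

    if coords == "image_px":
        pos = pos / units.px_per_mm
        if image_size is not None:
            cx = image_size[0] / units.px_per_mm / 2
            cy = image_size[1] / units.px_per_mm / 2
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cx = np.nanmean(pos[:, :, 0])
                cy = np.nanmean(pos[:, :, 1])
        pos[:, :, 0] -= cx
        pos[:, :, 1] = cy - pos[:, :, 1]  # flip image y-down to Cartesian y-up
    elif coords != "cartesian_mm":
        raise ValueError(f"unknown coords convention {coords!r}")

    if arena is not None:
        valid = ~np.isnan(pos).any(axis=2)
        sd = arena.signed_distance(pos[valid])
        n_out = int(np.sum(sd > boundary_tol_mm))
        if n_out:
            log.warning("%d tracked points lie > %g mm outside the arena", n_out, boundary_tol_mm)

    missing = np.isnan(pos).any(axis=2).mean(axis=1)
    for fid, frac in zip(fish_ids, missing):
        if frac > 0.05:
            log.warning("fish %s missing in %.1f%% of frames", fid, 100 * frac)

    bl = None
    if body_length_mm is not None:
        bl = np.array([body_length_mm.get(fid, MEAN_BODY_LENGTH_MM) for fid in fish_ids])
    return TrajectorySet(group_id, list(fish_ids), frames, pos, bl, units)


def write_trajectories(traj: TrajectorySet, path) -> None:
    """Write a trajectory set back to long CSV in package (mm, y-up) coords."""
    tracked = traj.tracked()
    recs = []
    for i, fid in enumerate(traj.fish_ids):
        ok = tracked[i]
        recs.append(
            pd.DataFrame(
                {
                    "frame": traj.frames[ok],
                    "id": fid,
                    "x": traj.positions[i, ok, 0],
                    "y": traj.positions[i, ok, 1],
                }
            )
        )
    pd.concat(recs).sort_values(["frame", "id"]).to_csv(path, index=False)


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs in a 1-D boolean mask."""
    idx = np.flatnonzero(np.diff(np.r_[False, mask, False].astype(int)))
    return list(zip(idx[::2], idx[1::2]))


def smooth_savgol(
    traj: TrajectorySet, window_frames: int = 13, degree: int = 3
) -> TrajectorySet:
    """Savitzky-Golay smoothing, applied per fish and per coordinate.

    The default window of 13 frames spans ~0.5 s at 25 fps with a cubic
    polynomial, matching common practice for reducing tracking jitter
    without distorting turns.  Runs shorter than the window are passed
    through unsmoothed (and logged); gaps are respected, never bridged.
    """
    if window_frames % 2 == 0:
        raise ValueError(
            f"window must be odd; use {window_frames - 1} or {window_frames + 1}"
        )
    if window_frames <= degree:
        raise ValueError("window must exceed the polynomial degree")
    out = traj.positions.copy()
    tracked = traj.tracked()
    for i in range(traj.n_fish):
        for start, stop in _contiguous_runs(tracked[i]):
            if stop - start < window_frames:
                log.debug(
                    "fish %s: run of %d frames < window %d left unsmoothed",
                    traj.fish_ids[i], stop - start, window_frames,
                )
                continue
            for c in (0, 1):
                out[i, start:stop, c] = savgol_filter(
                    traj.positions[i, start:stop, c], window_frames, degree
                )
    return replace(traj, positions=out, smoothed=True)
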