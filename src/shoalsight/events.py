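"""Stimulus presentations, first responses and arrivals.

A presentation is valid only if, at onset, every fish is at least 43 cm
from the port and on the opposite half of the arena, and the 0.5-s
pre-stimulus window is gap-free.  Within the 20-s (500-frame) window after
onset:

* a fish *responds* at the first frame where it is oriented towards the
  port (bearing below a threshold) and moving clearly faster than its own
  pre-stimulus median speed, both sustained for a few frames — a
  reconstruction of "oriented, accelerated movement toward the stimulus",
  with every threshold configurable;
* a fish *arrives* when it first comes within two body lengths of the
  port; arrival latencies rank the group's arrival order (1..8).

The first responder being the first arriver far more often than the 1/N
chance level is the signature of private detection paying off in scramble
competition; `first_responder_first_arriver` runs that exact binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import binomtest

from .arena import ArenaGeometry, StimulusPort
from .io import TrajectorySet
from .metrics import HeadingField, _bearings_frame

__all__ = [
    "Presentation",
    "ResponseCriteria",
    "ResponseEvent",
    "ArrivalEvent",
    "validate_presentation",
    "detect_responses",
    "arrival_events",
    "first_responder_first_arriver",
]

MAX_WINDOW_FRAMES = 500  # 20 s at 25 fps
PRE_WINDOW_FRAMES = 13  # 0.5 s at 25 fps
MIN_DIST_MM = 430.0


@dataclass
class Presentation:
    trial_id: str
    presentation_id: int
    onset_frame: int
    port: StimulusPort
    valid: bool = True
    exclusion_reason: str | None = None
    cumulative_days_of_testing: int = 0

    @property
    def port_position(self) -> np.ndarray:
        return np.asarray(self.port.position, dtype=float)


@dataclass(frozen=True)
class ResponseCriteria:
    max_window_frames: int = MAX_WINDOW_FRAMES
    bearing_threshold_deg: float = 30.0
    speed_factor: float = 1.5
    sustain_frames: int = 5

    def __post_init__(self) -> None:
        if min(self.max_window_frames, self.bearing_threshold_deg,
               self.speed_factor, self.sustain_frames) <= 0:
            raise ValueError("all response criteria must be positive")


@dataclass(frozen=True)
class ResponseEvent:
    presentation_id: int
    fish_id: int
    response_latency: int  # frames after onset, in (0, 500]


@dataclass(frozen=True)
class ArrivalEvent:
    presentation_id: int
    fish_id: int
    arrival_latency: int  # frames after onset, in (0, 500]
    arrival_order: int  # 1..N among arrivers


def validate_presentation(
    traj: TrajectorySet,
    presentation: Presentation,
    arena: ArenaGeometry,
    min_dist_mm: float = MIN_DIST_MM,
    pre_window_frames: int = PRE_WINDOW_FRAMES,
) -> Presentation:
    """Flag a presentation invalid rather than raising.

    Reasons, in order of checking: ``tracking-gap`` (pre-window or onset
    untracked), ``min-distance`` (any fish nearer than 43 cm to the port),
    ``same-half`` (any fish on the port's half of the long axis).
    """
    onset = presentation.onset_frame
    try:
        i0 = traj.frame_index(onset)
        sl = traj.window_slice(onset - pre_window_frames, pre_window_frames)
    except KeyError:
        return replace(presentation, valid=False, exclusion_reason="tracking-gap")
    tracked = traj.tracked()
    if not tracked[:, sl].all() or not tracked[:, i0].all():
        return replace(presentation, valid=False, exclusion_reason="tracking-gap")
    pos = traj.positions[:, i0]
    port = presentation.port_position
    dists = np.linalg.norm(pos - port, axis=1)
    if np.any(dists < min_dist_mm):
        return replace(presentation, valid=False, exclusion_reason="min-distance")
    # halves split along the short axis of the arena (x = 0); the stimulus
    # half is the sign of the port's x coordinate
    port_side = np.sign(port[0])
    if port_side != 0 and np.any(np.sign(pos[:, 0]) == port_side):
        return replace(presentation, valid=False, exclusion_reason="same-half")
    return replace(presentation, valid=True, exclusion_reason=None)


def detect_responses(
    traj: TrajectorySet,
    headings: HeadingField,
    presentation: Presentation,
    criteria: ResponseCriteria = ResponseCriteria(),
) -> list[ResponseEvent]:
    """Per-fish response latencies within the post-onset window.

    A fish responds at the first frame where bearing-to-port <
    ``bearing_threshold_deg`` AND speed > ``speed_factor`` x its own
    pre-stimulus median speed, both holding for ``sustain_frames``
    consecutive frames.  Fish that never meet the criteria contribute no
    event.  Sorted by latency (ties to the lower fish id), so the first
    element is the first responder.
    """
    onset = presentation.onset_frame
    i0 = traj.frame_index(onset)
    stop = min(i0 + criteria.max_window_frames + 1, traj.n_frames)
    port = presentation.port_position

    pre = traj.window_slice(onset - PRE_WINDOW_FRAMES, PRE_WINDOW_FRAMES)
    pre_speed = np.nanmedian(headings.speed[:, pre], axis=1)

    pos = traj.positions[:, i0 + 1: stop]
    h = headings.headings[:, i0 + 1: stop]
    speed = headings.speed[:, i0 + 1: stop]
    bearings = _bearings_frame(pos, h, port)

    with np.errstate(invalid="ignore"):
        ok = (bearings < criteria.bearing_threshold_deg) & (
            speed > criteria.speed_factor * pre_speed[:, None]
        )
    events = []
    k = criteria.sustain_frames
    for i, fid in enumerate(traj.fish_ids):
        row = ok[i]
        if row.size < k:
            continue
        run = np.convolve(row.astype(int), np.ones(k, dtype=int), mode="valid")
        hits = np.flatnonzero(run == k)
        if hits.size:
            events.append(ResponseEvent(presentation.presentation_id, fid, int(hits[0]) + 1))
    events.sort(key=lambda e: (e.response_latency, e.fish_id))
    return events


def arrival_events(
    traj: TrajectorySet,
    presentation: Presentation,
    body_lengths_mm: np.ndarray | None = None,
    max_window_frames: int = MAX_WINDOW_FRAMES,
) -> list[ArrivalEvent]:
    """Arrival latencies and order within the 20-s window.

    Arrival = first frame at distance <= 2 body lengths from the port;
    per-fish measured body length when available, the 27 mm cohort mean
    otherwise.  Simultaneous arrivals are ranked by distance at the shared
    frame, then fish id.
    """
    onset = presentation.onset_frame
    i0 = traj.frame_index(onset)
    stop = min(i0 + max_window_frames + 1, traj.n_frames)
    port = presentation.port_position
    bl = (np.asarray(body_lengths_mm, dtype=float)
          if body_lengths_mm is not None else traj.body_length_mm)

    dists = np.linalg.norm(traj.positions[:, i0 + 1: stop] - port, axis=2)
    with np.errstate(invalid="ignore"):
        within = dists <= (2.0 * bl)[:, None]
    raw = []
    for i, fid in enumerate(traj.fish_ids):
        hits = np.flatnonzero(within[i])
        if hits.size:
            lat = int(hits[0]) + 1
            raw.append((lat, float(dists[i, hits[0]]), fid))
    raw.sort()
    return [
        ArrivalEvent(presentation.presentation_id, fid, lat, rank)
        for rank, (lat, _, fid) in enumerate(raw, start=1)
    ]


def first_responder_first_arriver(
    responses: dict[int, list[ResponseEvent]],
    arrivals: dict[int, list[ArrivalEvent]],
    n_fish: int = 8,
) -> tuple[float, float, float, int]:
    """One-sided binomial test that first responders are first arrivers.

    Over presentations with both a first response and a first arrival,
    the observed proportion where one fish holds both roles is tested
    against the chance level 1/N (0.125 for groups of eight).

    Returns (observed proportion, null probability, one-sided p, n).
    """
    null = 1.0 / n_fish
    n = matches = 0
    for pid, resp in responses.items():
        arr = arrivals.get(pid, [])
        if not resp or not arr:
            continue
        n += 1
        if resp[0].fish_id == arr[0].fish_id:
            matches += 1
    if n == 0:
        raise ValueError("no presentation has both a first response and a first arrival")
    p = binomtest(matches, n, null, alternative="greater").pvalue
    return matches / n, null, float(p), n
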