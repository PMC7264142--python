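"""End-to-end processing: trajectories -> window metrics -> events -> tables.

This is the spine the analysis drivers, tests and acceptance checks share:
smooth the trajectories, derive displacement headings, validate each
presentation, summarize the pre-stimulus window, and extract response and
arrival events — returning tidy per-presentation and per-fish tables ready
for the inference layer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arena import ArenaGeometry
from .events import (
    ResponseCriteria,
    arrival_events,
    detect_responses,
    validate_presentation,
)
from .io import TrajectorySet, smooth_savgol
from .metrics import headings_from_displacement, nn_heading_difference, window_metrics
from .simulate import SimOutput
from .vision import VisionConfig, body_models, occlusion_index

__all__ = ["process_experiment", "presentation_tables", "window_occlusion"]


def window_occlusion(
    traj: TrajectorySet,
    field,
    arena: ArenaGeometry,
    config: VisionConfig,
    onset_frame: int,
    window_frames: int = 13,
) -> np.ndarray:
    """Median per-fish visual-occlusion index over the pre-stimulus window."""
    vals = np.full((traj.n_fish, window_frames), np.nan)
    for k, fr in enumerate(range(onset_frame - window_frames, onset_frame)):
        i = traj.frame_index(fr)
        pos = traj.positions[:, i]
        ang = np.arctan2(field.headings[:, i, 1], field.headings[:, i, 0])
        bodies = body_models(pos, ang, traj.body_length_mm, config,
                             fish_ids=list(range(traj.n_fish)))
        for f in range(traj.n_fish):
            if not np.isfinite(ang[f]):
                continue
            vals[f, k] = occlusion_index(
                pos[f], ang[f], traj.body_length_mm[f], bodies, arena, config,
                fish_id=f,
            )
    return np.nanmedian(vals, axis=1)


def presentation_tables(
    traj: TrajectorySet,
    presentations,
    arena: ArenaGeometry,
    criteria: ResponseCriteria = ResponseCriteria(),
    vision: VisionConfig | None = None,
    compute_occlusion: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Process presentations into (group table, individual table, arrival table).

    The trajectory is smoothed here; presentations failing validation are
    kept in the group table with their exclusion reason and contribute no
    events.  ``compute_occlusion`` adds the ray-cast occlusion index to the
    individual table (slower; off by default).
    """
    sm = smooth_savgol(traj) if not traj.smoothed else traj
    field = headings_from_displacement(sm)

    group_rows, indiv_rows, arrival_rows = [], [], []
    for pres in presentations:
        pres = validate_presentation(sm, pres, arena)
        row = {
            "trial_id": pres.trial_id,
            "presentation_id": pres.presentation_id,
            "onset_frame": pres.onset_frame,
            "port_id": pres.port.id,
            "valid": pres.valid,
            "exclusion_reason": pres.exclusion_reason,
            "cumulative_days_of_testing": pres.cumulative_days_of_testing,
        }
        if not pres.valid:
            group_rows.append(row)
            continue
        occl = None
        if compute_occlusion:
            occl = window_occlusion(sm, field, arena, vision or VisionConfig(),
                                    pres.onset_frame)
        indiv, group = window_metrics(sm, field, pres.port_position,
                                      pres.onset_frame, occlusion=occl)
        if indiv is None:
            row.update(valid=False, exclusion_reason="tracking-gap")
            group_rows.append(row)
            continue
        responses = detect_responses(sm, field, pres, criteria)
        arrivals = arrival_events(sm, pres)
        row.update(group)
        row["first_responder_id"] = responses[0].fish_id if responses else None
        row["first_response_latency"] = responses[0].response_latency if responses else None
        row["first_arriver_id"] = arrivals[0].fish_id if arrivals else None
        group_rows.append(row)

        resp_by_fish = {e.fish_id: e.response_latency for e in responses}
        indiv = indiv.assign(
            trial_id=pres.trial_id,
            presentation_id=pres.presentation_id,
            response_latency=[
                float(resp_by_fish.get(f, np.nan)) for f in indiv["fish_id"]
            ],
            is_first_responder=[
                int(responses[0].fish_id == f) if responses else 0
                for f in indiv["fish_id"]
            ],
        )
        indiv_rows.append(indiv)
        for e in arrivals:
            arrival_rows.append(
                {
                    "trial_id": pres.trial_id,
                    "presentation_id": pres.presentation_id,
                    "fish_id": e.fish_id,
                    "arrival_latency": e.arrival_latency,
                    "arrival_order": e.arrival_order,
                    "polarization": group["polarization"],
                    "group_bearing_stimulus": group["group_bearing_stimulus"],
                    "centroid_dist_stimulus": group["centroid_dist_stimulus"],
                    "cumulative_days_of_testing": pres.cumulative_days_of_testing,
                }
            )

    group_df = pd.DataFrame(group_rows)
    indiv_df = (pd.concat(indiv_rows, ignore_index=True)
                if indiv_rows else pd.DataFrame())
    arrivals_df = pd.DataFrame(arrival_rows)
    return group_df, indiv_df, arrivals_df


def process_experiment(
    out: SimOutput,
    arena: ArenaGeometry | None = None,
    criteria: ResponseCriteria = ResponseCriteria(),
    vision: VisionConfig | None = None,
    compute_occlusion: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full measurement pipeline on a simulated experiment."""
    from .arena import default_arena

    return presentation_tables(
        out.traj, out.presentations, arena or default_arena(),
        criteria=criteria, vision=vision, compute_occlusion=compute_occlusion,
    )


def mean_nn_heading_table(
    traj: TrajectorySet, onset_frames: list[int], pre_s: float = 180.0,
    fps: float = 25.0,
) -> pd.DataFrame:
    """Per-fish mean nearest-neighbour heading difference and mean speed.

    Averaged over every frame in the ``pre_s`` seconds before each onset
    (the out-of-foraging-context baseline behaviour).
    """
    sm = smooth_savgol(traj) if not traj.smoothed else traj
    field = headings_from_displacement(sm)
    n_pre = int(round(pre_s * fps))
    diffs = np.zeros(traj.n_fish)
    speeds = np.zeros(traj.n_fish)
    counts = np.zeros(traj.n_fish)
    scounts = np.zeros(traj.n_fish)
    for onset in onset_frames:
        start = max(int(traj.frames[0]), onset - n_pre)
        for fr in range(start, onset):
            try:
                d = nn_heading_difference(sm, field, fr)
            except KeyError:
                continue
            ok = np.isfinite(d)
            diffs[ok] += d[ok]
            counts[ok] += 1
            i = sm.frame_index(fr)
            sp = field.speed[:, i]
            oks = np.isfinite(sp)
            speeds[oks] += sp[oks]
            scounts[oks] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return pd.DataFrame(
            {
                "fish_id": traj.fish_ids,
                "mean_nn_heading_diff": diffs / np.maximum(counts, 1),
                "mean_speed": speeds / np.maximum(scounts, 1),
            }
        )
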