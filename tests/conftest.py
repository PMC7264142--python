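"""Shared fixtures: arena, simulated window pool, simulated experiment pool.

The heavier fixtures are session-scoped and shared across test modules so
the suite stays inside a desk-scale budget: one pool of short schooling
windows spanning the order range (for dispersion/coverage statistics) and
one pool of full detection experiments (for event and inference checks).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from shoalsight.arena import default_arena
from shoalsight.io import TrajectorySet, smooth_savgol
from shoalsight.metrics import headings_from_displacement, window_metrics
from shoalsight.pipeline import process_experiment
from shoalsight.simulate import SimConfig, apply_detection_model


@pytest.fixture(scope="session")
def arena():
    return default_arena()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def _simulate_window(seed: int, w_align: float, arena, n_frames: int = 300):
    """One pre-stimulus window: short schooling run + metrics at its end."""
    from shoalsight.simulate import simulate_shoal

    cfg = SimConfig(seed=seed, w_align=w_align)
    traj, theta = simulate_shoal(cfg, n_frames=n_frames)
    port = arena.ports[seed % len(arena.ports)]
    sm = smooth_savgol(traj)
    field = headings_from_displacement(sm)
    indiv, group = window_metrics(sm, field, np.asarray(port.position), n_frames - 1)
    return {
        "traj": traj,
        "theta": theta,
        "positions_end": traj.positions[:, n_frames - 2],
        "theta_end": theta[:, n_frames - 2],
        "body_length": traj.body_length_mm,
        "port": port,
        "indiv": indiv,
        "group": group,
    }


@pytest.fixture(scope="session")
def window_pool(arena):
    """400 simulated pre-stimulus windows spanning the order range."""
    rng = np.random.default_rng(2024)
    rows = []
    for k in range(400):
        w = float(rng.uniform(-1.0, 5.0))
        win = _simulate_window(seed=5000 + k, w_align=w, arena=arena)
        if win["group"] is None:
            continue
        rows.append(win)
    return rows


@pytest.fixture(scope="session")
def window_table(window_pool):
    return pd.DataFrame(
        [
            {
                "polarization": w["group"]["polarization"],
                "bearing_sd": w["group"]["bearing_sd"],
                "min_bearing": w["group"]["min_bearing"],
            }
            for w in window_pool
        ]
    ).dropna()


@pytest.fixture(scope="session")
def experiment_pool(arena):
    """Detection experiments across the order range, processed end to end.

    90 simulated trials of up to 5 presentations each (inter-presentation
    gap shortened from the experimental 3 min to keep the suite fast; the
    default-protocol gap is tested separately).  Returns per-trial tuples
    of (SimOutput, group table, individual table, arrival table).
    """
    rng = np.random.default_rng(77)
    out = []
    for k in range(90):
        w = float(rng.uniform(-1.0, 6.0))
        cfg = SimConfig(seed=20_000 + k, w_align=w)
        sim = apply_detection_model(cfg, n_presentations=5, min_gap_s=12,
                                    group_id=f"g{k:02d}", trial_id=f"g{k:02d}",
                                    cumulative_days=k % 20)
        g, i, a = process_experiment(sim, arena=arena)
        for df in (g, i, a):
            if len(df):
                df["group_id"] = f"g{k:02d}"
        out.append((sim, g, i, a))
    return out


@pytest.fixture(scope="session")
def arrivals_table(experiment_pool):
    """Pooled arrival rows with log latency and unique fish ids."""
    frames = [a for (_, _, _, a) in experiment_pool if len(a)]
    arr = pd.concat(frames, ignore_index=True)
    arr["log_latency"] = np.log10(arr["arrival_latency"])
    arr["uid"] = arr["group_id"] + ":" + arr["fish_id"].astype(str)
    return arr


@pytest.fixture(scope="session")
def group_table(experiment_pool):
    frames = [g for (_, g, _, _) in experiment_pool if len(g)]
    g = pd.concat(frames, ignore_index=True)
    return g[g["valid"]].reset_index(drop=True)


def straight_trajectory(n_fish=2, n_frames=60, speed=5.0, origin=(-300.0, 0.0),
                        spacing=40.0):
    """Deterministic straight-line swim along +x, fish stacked in y."""
    frames = np.arange(n_frames)
    pos = np.zeros((n_fish, n_frames, 2))
    for i in range(n_fish):
        pos[i, :, 0] = origin[0] + speed * frames
        pos[i, :, 1] = origin[1] + i * spacing
    return TrajectorySet("toy", list(range(1, n_fish + 1)), frames, pos)
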