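"""Pre-stimulus window metrics for every simulated presentation.

Reads the trajectories written by 01_simulate_shoals.py, validates each
presentation (43-cm rule, opposite half, gap-free pre-window), and computes
the individual parameters (speed, distance and bearing to the stimulus,
hull-edge proportion, centroid distance, body length — plus their
group-relative values) and group parameters (hull area, group bearing,
centroid distance and speed, polarization, bearing dispersion) over the
0.5-s window before onset, together with response and arrival events.

Writes:
    results/metrics_group.csv        one row per presentation
    results/metrics_individual.csv   one row per fish per presentation
    results/arrivals.csv             one row per arriving fish
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from shoalsight.arena import default_arena  # noqa: E402
from shoalsight.events import Presentation  # noqa: E402
from shoalsight.io import read_trajectories  # noqa: E402
from shoalsight.pipeline import presentation_tables  # noqa: E402

SIM = ROOT / "scratch" / "sim"
arena = default_arena()
ports = {p.id: p for p in arena.ports}

groups, indivs, arrivals = [], [], []
for pres_path in sorted(SIM.glob("*_presentations.csv")):
    tid = pres_path.name.replace("_presentations.csv", "")
    try:
        pres_df = pd.read_csv(pres_path)
    except pd.errors.EmptyDataError:
        continue  # trial ended before any presentation became eligible
    traj = read_trajectories(SIM / f"{tid}_traj.csv", coords="cartesian_mm",
                             group_id=tid.split("_t")[0])
    pres = [
        Presentation(r.trial_id, int(r.presentation_id), int(r.onset_frame),
                     ports[int(r.port_id)],
                     cumulative_days_of_testing=int(r.cumulative_days_of_testing))
        for r in pres_df.itertuples()
    ]
    g, i, a = presentation_tables(traj, pres, arena)
    for df in (g, i, a):
        if len(df):
            df.insert(0, "group_id", tid.split("_t")[0])
    groups.append(g)
    if len(i):
        indivs.append(i)
    if len(a):
        arrivals.append(a)

if not groups:
    raise SystemExit("no simulated trials found; run 01_simulate_shoals.py first")

g = pd.concat(groups, ignore_index=True)
i = pd.concat(indivs, ignore_index=True)
a = pd.concat(arrivals, ignore_index=True)
g.to_csv(ROOT / "results" / "metrics_group.csv", index=False, float_format="%.4f")
i.to_csv(ROOT / "results" / "metrics_individual.csv", index=False, float_format="%.4f")
a.to_csv(ROOT / "results" / "arrivals.csv", index=False, float_format="%.4f")

valid = g[g["valid"]]
print(f"{len(g)} presentations processed, {len(valid)} valid "
      f"({(~g['valid']).sum()} excluded: "
      f"{g.loc[~g['valid'], 'exclusion_reason'].value_counts().to_dict()})")
print(f"window polarization spans {valid.polarization.min():.2f}-"
      f"{valid.polarization.max():.2f}; {len(a)} arrival events")
print("tables in results/metrics_group.csv, metrics_individual.csv, arrivals.csv")
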