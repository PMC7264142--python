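"""Multimodel inference on the simulated experiment.

Three analyses mirroring the study design:

1. First-response latency: all-subsets AICc candidate models over the
   standardized group parameters (with a group random intercept), full
   model averaging over the 95% cumulative-weight set, and the relative
   importance of each parameter — is polarization a dominant predictor?
2. Arrival latency: the LMM of log10 latency with the polarization x
   arrival-order interaction (fish nested in group, Cook's-distance
   screen at six times the mean) — does the crossover appear?
3. Repeatability of arrival order (sqrt-transformed) across presentations.

Writes results/model_averaging.csv, results/arrival_model.csv,
results/repeatability.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from shoalsight.inference import (  # noqa: E402
    ModelSpec,
    all_subsets,
    cooks_filter,
    fit_model,
    full_model_average,
    repeatability,
    standardize,
)

g = pd.read_csv(ROOT / "results" / "metrics_group.csv")
a = pd.read_csv(ROOT / "results" / "arrivals.csv")

# --- 1. what predicts the speed of the first response? ---------------------
gg = g[g["valid"]].dropna(subset=["first_response_latency"]).copy()
gg["log_first_latency"] = np.log10(gg["first_response_latency"])
params = ["polarization", "group_bearing_stimulus", "centroid_dist_stimulus",
          "hull_area", "centroid_speed"]
gg, _ = standardize(gg, params)
cs = all_subsets(
    ModelSpec(response="log_first_latency", fixed=tuple(params),
              random={"group": "group_id"}),
    gg,
)
avg = full_model_average(cs)
avg.estimates.to_csv(ROOT / "results" / "model_averaging.csv", index=False)
print(f"first-response latency: {len(cs.models)} candidate models on "
      f"n={len(gg)} presentations; averaging over the top {avg.subset_size} "
      f"(cumulative weight {avg.subset_cumweight:.3f})")
print(avg.estimates.round(3).to_string(index=False))
q = g[g["valid"]]["polarization"].quantile([0.1, 0.5, 0.9]).round(2).tolist()
print(f"note: presentation eligibility (whole group on one half) favours "
      f"cohesive, transiting shoals — window polarization deciles {q}; "
      f"low-order windows are under-sampled at this demo size, diluting "
      f"polarization's relative importance")

# --- 2. the polarization x arrival-order crossover -------------------------
a["log_latency"] = np.log10(a["arrival_latency"])
a["uid"] = a["group_id"] + ":" + a["fish_id"].astype(str)
spec = ModelSpec(
    response="log_latency",
    fixed=("polarization", "arrival_order", "group_bearing_stimulus",
           "centroid_dist_stimulus", "cumulative_days_of_testing"),
    interactions=("polarization:arrival_order",),
    random={"group": "group_id", "individual": "uid"},
)
kept, removed = cooks_filter(spec, a, factor=6.0)
fit = fit_model(spec, kept)
coefs = pd.DataFrame({"term": fit.params.index, "estimate": fit.params.values,
                      "se": fit.bse.reindex(fit.params.index).values})
coefs.to_csv(ROOT / "results" / "arrival_model.csv", index=False)
beta = float(fit.params["polarization:arrival_order"])
se = float(fit.bse["polarization:arrival_order"])
print(f"\narrival latency LMM (n={len(kept)}, {len(removed)} Cook's-distance "
      f"outliers removed): polarization x arrival order = {beta:+.4f} +- {se:.4f}")

# --- 3. are individuals consistent in their arrival order? -----------------
a["sqrt_order"] = np.sqrt(a["arrival_order"])
rpt = repeatability(a, "sqrt_order", individual="uid", group="group_id",
                    n_boot=200, seed=1)
pd.DataFrame(
    [{"R": rpt.R, "ci_lo": rpt.ci[0], "ci_hi": rpt.ci[1], "p_lrt": rpt.p_lrt}]
).to_csv(ROOT / "results" / "repeatability.csv", index=False)
print(f"arrival-order repeatability: R = {rpt.R:.2f} "
      f"(95% CI {rpt.ci[0]:.2f}-{rpt.ci[1]:.2f}, LRT p = {rpt.p_lrt:.1e})")
print("tables in results/model_averaging.csv, arrival_model.csv, repeatability.csv")
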