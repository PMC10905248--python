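"""Fit a maximum-entropy niche model to synthetic occurrences and evaluate it.

Builds a small landscape with known truth (suitability rises with the
temperature-like layer env01), samples biased presences, prepares them the way
field data are prepared (cleaning, 5-km thinning, target-group background),
selects the regularization multiplier by AICc, and cross-validates.
"""

import numpy as np

from nicheshift import (
    BiasSurface,
    TruthSpec,
    build_bias_surface,
    clean_records,
    cross_validate,
    make_env_stack,
    make_truth_and_sample,
    sample_background,
    select_rm,
    thin_by_grid,
)
from nicheshift.grid import RasterGrid
from nicheshift.occurrences import LAT, LON

grid = RasterGrid(40, 40, 0.05, x_min=-105.0, y_max=42.0)
stack = make_env_stack(grid, n_layers=6, pairwise_corr=0.0, seed=1)

truth = TruthSpec(stack.layer_names, {"env01": 2.0}, seed=2)
# presences are drawn with spatially uneven sampling effort, as field
# records are: probability ~ suitability x effort
from nicheshift import make_bias_field

effort = make_bias_field(grid, strength=0.8, seed=3)
_, raw_occ = make_truth_and_sample(
    stack, truth, n_presence=400, bias=effort, species="demo"
)
print(f"raw records: {len(raw_occ)} (includes injected dirty rows)")

occ = clean_records(raw_occ)
occ = thin_by_grid(occ, grid, cell_km=5.0, seed=3)
print(f"after cleaning + 5-km thinning: {len(occ)} records")

# pseudo-absences drawn with the same sampling effort (the target-group idea:
# the background replicates the presences' spatial bias, so the model fits the
# species' response rather than the surveyors' habits)
background = sample_background(effort, n=10_000, seed=4)

pres_env = stack.values_at(occ[LON], occ[LAT])
bg_env = stack.values_at(background[LON], background[LAT])

best_rm, table = select_rm(pres_env, bg_env, [0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
print(f"\nAICc-selected regularization multiplier: {best_rm}")
print(table.round(2).to_string(index=False))

cv = cross_validate(pres_env, bg_env, k=5, rm=best_rm, seed=5)
print(f"\n5-fold AUCs: {[round(a, 3) for a in cv.fold_aucs]}")
print(f"mean AUC = {cv.mean_auc:.3f}  (0.5 = random discrimination)")

contrib = cv.models[0].contributions
top = sorted(contrib.items(), key=lambda kv: -kv[1])[:3]
print("\ntop percent contributions (fold-1 model):")
for name, pct in top:
    print(f"  {name}: {pct:.1f}%")
print("env01 drives the truth, so it should dominate the contributions.")
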