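"""Schoener's D and Warren's I between two suitability surfaces.

Two species share a landscape but differ in their response to one layer; the
overlap metrics quantify how similar their normalized suitability surfaces
are (0 = disjoint niches, 1 = identical). I is always >= D.
"""

from nicheshift import (
    TruthSpec,
    make_env_stack,
    normalize_surface,
    schoener_d,
    true_suitability,
    warren_i,
)
from nicheshift.grid import RasterGrid

grid = RasterGrid(40, 40, 0.05, x_min=-105.0, y_max=42.0)
stack = make_env_stack(grid, n_layers=4, seed=10)

# a shared moisture response, diverging temperature responses
predator = TruthSpec(stack.layer_names, {"env01": -1.0, "env03": 1.5})
prey = TruthSpec(stack.layer_names, {"env01": 0.5, "env03": 1.5})

map_a = true_suitability(stack, predator)
map_b = true_suitability(stack, prey)
shared = map_a.mask & map_b.mask
pa, pb = normalize_surface(map_a, shared), normalize_surface(map_b, shared)

d = schoener_d(pa, pb)
i = warren_i(pa, pb)
print(f"Schoener's D = {d:.3f}")
print(f"Warren's I   = {i:.3f}")
print("High values mean the pair occupies similar abiotic conditions;")
print(f"I >= D always holds (here {i:.3f} >= {d:.3f}).")

identical = schoener_d(pa, pa)
print(f"self-overlap sanity check: D(p, p) = {identical:.1f}")
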