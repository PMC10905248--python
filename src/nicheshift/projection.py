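"""Scenario projection: predict a fitted model onto per-GCM climate stacks and
ensemble-average the suitability maps within each scenario.

A scenario bundles one climate stack per global circulation model (GCM) plus
the static layers (terrain, soil) that are held constant across periods. The
ensemble average operates on model *outputs* (suitability), not on averaged
climate inputs; averaging in layer space is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import RasterStack
from .maxent import MaxentModel, SuitabilityMap, predict_map, predict_map_ensemble

__all__ = ["ScenarioSet", "merge_stacks", "project_scenario", "average_gcms"]


@dataclass
class ScenarioSet:
    """One labelled scenario: per-GCM climate stacks plus shared static layers."""

    label: str
    gcm_stacks: dict[str, RasterStack]
    static: RasterStack | None = None

    def __post_init__(self) -> None:
        if not self.gcm_stacks:
            raise ValueError("scenario needs at least one GCM stack")
        grids = [s.grid for s in self.gcm_stacks.values()]
        if self.static is not None:
            grids.append(self.static.grid)
        first = grids[0]
        if not all(first.same_frame(g) for g in grids[1:]):
            raise ValueError("all scenario stacks must share one grid")

    def merged(self, gcm: str) -> RasterStack:
        return merge_stacks(self.gcm_stacks[gcm], self.static)


def merge_stacks(climate: RasterStack, static: RasterStack | None) -> RasterStack:
    """Union of climate and static layers on one grid (mask = intersection)."""
    out = climate.copy()
    if static is not None:
        for name in static.layer_names:
            if name not in out:
                out.add_layer(name, static[name])
    return out


def project_scenario(
    models: MaxentModel | list[MaxentModel],
    scenario: ScenarioSet,
    clamp: bool = True,
    scale: str = "cloglog",
) -> dict[str, SuitabilityMap]:
    """One suitability map per GCM. ``models`` may be a single fit or the list
    of cross-validation replicates (averaged cell-wise, the default pipeline
    behaviour)."""
    mdls = models if isinstance(models, list) else [models]
    needed = mdls[0].feature_set.variables
    out: dict[str, SuitabilityMap] = {}
    for gcm in scenario.gcm_stacks:
        stack = scenario.merged(gcm)
        missing = [v for v in needed if v not in stack]
        if missing:
            raise KeyError(
                f"scenario {scenario.label!r} GCM {gcm!r} lacks layer(s): {missing}"
            )
        out[gcm] = predict_map_ensemble(mdls, stack, clamp=clamp, scale=scale)
    return out


def average_gcms(maps: dict[str, SuitabilityMap]) -> SuitabilityMap:
    """Cell-wise arithmetic mean over GCM maps.

    All maps must share grid and scale; a cell is nodata iff it is nodata in
    any input (strict intersection), so scenario sums are always computed over
    one common footprint.
    """
    if not maps:
        raise ValueError("no maps to average")
    # canonical (name-sorted) summation order: permutation-exact averaging
    vals = [maps[k] for k in sorted(maps)]
    first = vals[0]
    for m in vals[1:]:
        if m.scale != first.scale:
            raise ValueError(f"mixed scales: {m.scale!r} vs {first.scale!r}")
        if not m.grid.same_frame(first.grid):
            raise ValueError("GCM maps are on different grids")
    stackd = np.array([m.values for m in vals])
    mean = stackd.mean(axis=0)  # nan wherever any input is nan
    return SuitabilityMap(first.grid, mean, first.scale)
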