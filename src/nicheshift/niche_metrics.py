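"""Abiotic niche overlap (Schoener's D, Warren's I) and the threshold-free
vulnerability assessment.

Overlap metrics compare two suitability surfaces normalized to probability
distributions over a shared validity mask:

    D = 1 - 1/2 * sum_i |pX_i - pY_i|
    I = 1 - 1/2 * sum_i (sqrt(pX_i) - sqrt(pY_i))^2

Both range from 0 (disjoint) to 1 (identical), and I >= D always. The
vulnerability assessment reports percent change in summed suitability H
between periods, per species and combined over the ranges' geometric
intersection — no suitability threshold is ever applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .grid import RasterGrid
from .maxent import SuitabilityMap
from .rasters import RangeArea

__all__ = [
    "ProbabilitySurface",
    "normalize_surface",
    "schoener_d",
    "warren_i",
    "intersect_ranges",
    "habitat_change",
    "combined_change",
    "VulnerabilityReport",
    "vulnerability_report",
]


@dataclass
class ProbabilitySurface:
    """A suitability surface normalized to sum 1 over its valid cells."""

    grid: RasterGrid
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != self.grid.shape:
            raise ValueError("p shape does not match grid")
        valid = self.p[np.isfinite(self.p)]
        if np.any(valid < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(valid.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 over valid cells")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.p)


def normalize_surface(
    s_map: SuitabilityMap, shared_mask: np.ndarray | None = None
) -> ProbabilitySurface:
    """Normalize a suitability map to a probability surface over a mask."""
    mask = s_map.mask if shared_mask is None else (s_map.mask & shared_mask)
    vals = np.where(mask, s_map.values, 0.0)
    total = vals.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero suitability map")
    p = np.full(s_map.grid.shape, np.nan)
    p[mask] = vals[mask] / total
    return ProbabilitySurface(s_map.grid, p)


def _check_pair(px: ProbabilitySurface, py: ProbabilitySurface) -> np.ndarray:
    if not px.grid.same_frame(py.grid):
        raise ValueError("surfaces are on different grids")
    if not np.array_equal(px.mask, py.mask):
        raise ValueError("surfaces have different validity masks")
    return px.mask


def schoener_d(px: ProbabilitySurface, py: ProbabilitySurface) -> float:
    """Schoener's D = 1 - 1/2 sum |pX - pY| over the shared mask."""
    mask = _check_pair(px, py)
    return float(1.0 - 0.5 * np.abs(px.p[mask] - py.p[mask]).sum())


def warren_i(px: ProbabilitySurface, py: ProbabilitySurface) -> float:
    """Warren's I = 1 - 1/2 sum (sqrt(pX) - sqrt(pY))^2 (Hellinger-based)."""
    mask = _check_pair(px, py)
    return float(1.0 - 0.5 * ((np.sqrt(px.p[mask]) - np.sqrt(py.p[mask])) ** 2).sum())


def intersect_ranges(a: RangeArea, b: RangeArea) -> BaseGeometry:
    """Geometric intersection of the two (buffered) ranges; empty is allowed."""
    ga, gb = a.buffered(), b.buffered()
    for g in (ga, gb):
        if not g.is_valid:  # pragma: no cover - RangeArea repairs on entry
            g = make_valid(g)
    inter = ga.intersection(gb)
    if inter.is_empty:
        warnings.warn(f"ranges of {a.species!r} and {b.species!r} do not overlap")
    return inter


def habitat_change(h_new: float, h_ref: float) -> float:
    """Percent change 100*(H_new - H_ref)/H_ref; negative = habitat loss."""
    if h_ref <= 0:
        raise ValueError("reference suitability sum must be positive")
    return 100.0 * (h_new - h_ref) / h_ref


def combined_change(hp_new: float, ho_new: float, hp_ref: float, ho_ref: float) -> float:
    """Combined two-species percent change over the co-occurrence area:
    100*((HP_new + HO_new) - (HP_ref + HO_ref))/(HP_ref + HO_ref)."""
    ref = hp_ref + ho_ref
    if ref <= 0:
        raise ValueError("combined reference suitability sum must be positive")
    return 100.0 * ((hp_new + ho_new) - ref) / ref


@dataclass
class VulnerabilityReport:
    """Percent changes in summed suitability per species and scenario, plus the
    combined change over the co-occurrence (range-intersection) area.

    ``h_values`` keeps every H used so each percent entry is reproducible from
    the stored sums.
    """

    changes: pd.DataFrame  # rows: species + "Overlap area"; columns: scenarios
    h_values: dict[str, dict[str, float]]

    def to_json_dict(self) -> dict:
        return {
            "changes": {
                row: {col: self.changes.loc[row, col] for col in self.changes.columns}
                for row in self.changes.index
            },
            "h_values": self.h_values,
        }


def vulnerability_report(
    current: dict[str, SuitabilityMap],
    scenarios: dict[str, dict[str, SuitabilityMap]],
    overlap_mask: np.ndarray,
    past_labels: set[str] | frozenset[str] = frozenset(),
    precision: int = 2,
) -> VulnerabilityReport:
    """Assemble the vulnerability table for a two-species pair.

    Future scenarios report current-to-future change, 100*(Hf-Hc)/Hc; labels
    in ``past_labels`` (paleo periods) report past-to-current change,
    100*(Hc-Hp)/Hp, so every entry reads "change relative to the past state".

    Parameters
    ----------
    current
        Current-conditions suitability map per species (exactly two).
    scenarios
        scenario label -> species -> projected suitability map (GCM-averaged),
        all on the same scale as ``current``.
    overlap_mask
        Boolean cell mask of the range-intersection (co-occurrence) area.
    """
    species = list(current)
    if len(species) != 2:
        raise ValueError("the vulnerability assessment is defined for a species pair")
    for label, per_species in scenarios.items():
        for sp, m in per_species.items():
            if m.scale != current[sp].scale:
                raise ValueError(
                    f"scale mismatch: scenario {label!r}/{sp!r} is {m.scale!r}, "
                    f"current is {current[sp].scale!r}"
                )
    h: dict[str, dict[str, float]] = {
        "current": {sp: current[sp].total() for sp in species},
        "current_overlap": {sp: current[sp].total(overlap_mask) for sp in species},
    }
    rows: dict[str, dict[str, float]] = {sp: {} for sp in species}
    rows["Overlap area"] = {}
    sp_a, sp_b = species
    for label, per_species in scenarios.items():
        h[label] = {sp: per_species[sp].total() for sp in species}
        h[f"{label}_overlap"] = {
            sp: per_species[sp].total(overlap_mask) for sp in species
        }
        is_past = label in past_labels
        for sp in species:
            new, ref = (
                (h["current"][sp], h[label][sp])
                if is_past
                else (h[label][sp], h["current"][sp])
            )
            rows[sp][label] = round(habitat_change(new, ref), precision)
        if is_past:
            combo = combined_change(
                h["current_overlap"][sp_a],
                h["current_overlap"][sp_b],
                h[f"{label}_overlap"][sp_a],
                h[f"{label}_overlap"][sp_b],
            )
        else:
            combo = combined_change(
                h[f"{label}_overlap"][sp_a],
                h[f"{label}_overlap"][sp_b],
                h["current_overlap"][sp_a],
                h["current_overlap"][sp_b],
            )
        rows["Overlap area"][label] = round(combo, precision)
    changes = pd.DataFrame(rows).T.loc[species + ["Overlap area"]]
    return VulnerabilityReport(changes, h)
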