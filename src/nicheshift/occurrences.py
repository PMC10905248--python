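"""Occurrence preparation: cleaning, grid thinning, target-group sampling-bias
surfaces, and weighted pseudo-absence (background) draws.

Occurrence tables are pandas DataFrames with at least ``decimalLongitude`` and
``decimalLatitude`` columns (Darwin Core names); ``species`` and ``taxonRank``
are used by the cleaning filters when present. Thinning mimics the common
"temporary 5 km x 5 km grid" protocol: one survivor per occupied thinning
cell, chosen uniformly at random under a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import M_PER_DEG, RasterGrid

__all__ = [
    "BiasSurface",
    "clean_records",
    "thin_by_grid",
    "build_bias_surface",
    "sample_background",
]

LON, LAT = "decimalLongitude", "decimalLatitude"

#: ranks treated as infraspecific and removed by the subspecies filter
SUBSPECIFIC_RANKS = {"subspecies", "variety", "form", "infraspecies"}


@dataclass
class BiasSurface:
    """Per-cell sampling-effort weights on the model grid (target-group bias file)."""

    grid: RasterGrid
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.grid.shape:
            raise ValueError("weights shape does not match grid")
        if np.any(self.weights < 0):
            raise ValueError("bias weights must be nonnegative")
        if self.weights.sum() <= 0:
            raise ValueError("bias surface has zero total weight")


def clean_records(
    raw: pd.DataFrame,
    drop_subspecies: bool = True,
    datum_transform: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Apply the three standard occurrence filters, preserving survivor order.

    Drops rows with a missing coordinate, rows whose ``taxonRank`` marks an
    infraspecific record (when ``drop_subspecies``), and exact duplicates of
    (species, lon, lat). ``datum_transform`` is a hook for datum conversion
    (e.g. NAD27 to WGS84) applied before filtering; default is identity.
    """
    missing = [c for c in (LON, LAT) if c not in raw.columns]
    if missing:
        raise ValueError(f"occurrence table lacks columns: {missing}")
    df = raw.copy()
    if datum_transform is not None:
        df = datum_transform(df)
    df = df[df[LON].notna() & df[LAT].notna()]
    if drop_subspecies and "taxonRank" in df.columns:
        rank = df["taxonRank"].astype(str).str.lower().str.strip()
        df = df[~rank.isin(SUBSPECIFIC_RANKS)]
    subset = [c for c in ("species", LON, LAT) if c in df.columns]
    df = df.drop_duplicates(subset=subset, keep="first")
    if len(df) == 0:
        warnings.warn("no occurrence records survived cleaning")
    return df.reset_index(drop=True)


def thinning_cell_size_deg(cell_km: float, mid_latitude: float) -> tuple[float, float]:
    """(dx, dy) in degrees of a cell_km-sided cell at the given latitude."""
    dy = cell_km * 1000.0 / M_PER_DEG
    dx = cell_km * 1000.0 / (M_PER_DEG * np.cos(np.radians(mid_latitude)))
    return dx, dy


def thin_by_grid(
    occ: pd.DataFrame,
    grid: RasterGrid,
    cell_km: float = 5.0,
    seed: int = 0,
    cell_deg: float | None = None,
) -> pd.DataFrame:
    """Spatial thinning: keep one record per occupied thinning-grid cell.

    The thinning grid is anchored at the raster grid origin; its cell edge is
    ``cell_km`` converted to degrees at the study-area mid-latitude, or the
    fixed ``cell_deg`` if given. The survivor per cell is chosen uniformly at
    random under ``seed`` so the result does not depend on input file order.
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    if cell_deg is not None:
        dx = dy = cell_deg
    else:
        dx, dy = thinning_cell_size_deg(cell_km, grid.mid_latitude)
    cx = np.floor((occ[LON].to_numpy(float) - grid.x_min) / dx).astype(int)
    cy = np.floor((grid.y_max - occ[LAT].to_numpy(float)) / dy).astype(int)
    cells = pd.Series(list(zip(cy, cx)), index=occ.index)
    rng = np.random.default_rng(seed)
    keep_idx = []
    for _, idx in cells.groupby(cells, sort=True).groups.items():
        keep_idx.append(rng.choice(np.asarray(idx)))
    keep_idx = sorted(keep_idx)
    return occ.loc[keep_idx].reset_index(drop=True)


def build_bias_surface(
    target_group: pd.DataFrame, grid: RasterGrid, smooth_cells: float = 0.0
) -> BiasSurface:
    """Target-group sampling-effort surface: per-cell record counts, optionally
    Gaussian-smoothed (bandwidth in cells) with the total mass preserved.
    """
    if len(target_group) == 0:
        raise ValueError(
            "no target-group records: fall back to a uniform background "
            "(BiasSurface(grid, np.ones(grid.shape)))"
        )
    row, col = grid.cell_index(target_group[LON].to_numpy(), target_group[LAT].to_numpy())
    inside = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
    counts = np.zeros(grid.shape)
    np.add.at(counts, (row[inside], col[inside]), 1.0)
    if counts.sum() <= 0:
        raise ValueError(
            "no target-group records fall inside the grid: fall back to a "
            "uniform background"
        )
    if smooth_cells > 0:
        total = counts.sum()
        counts = ndimage.gaussian_filter(counts, sigma=smooth_cells, mode="constant")
        counts *= total / counts.sum()  # renormalize edge truncation
    return BiasSurface(grid, counts)


def sample_background(
    bias: BiasSurface,
    n: int = 10_000,
    seed: int = 0,
    species: str = "background",
) -> pd.DataFrame:
    """Draw ``n`` pseudo-absence points with cell probability proportional to
    the bias weights (multinomial, with replacement across cells) and uniform
    placement within each chosen cell.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    w = bias.weights.ravel()
    p = w / w.sum()
    counts = rng.multinomial(n, p)
    rows, cols = np.unravel_index(np.repeat(np.arange(w.size), counts), bias.grid.shape)
    g = bias.grid
    lon = g.x_min + (cols + rng.random(n)) * g.cell_size
    lat = g.y_max - (rows + rng.random(n)) * g.cell_size
    return pd.DataFrame(
        {"species": species, LON: lon, LAT: lat, "taxonRank": "background"}
    )
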