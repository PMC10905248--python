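"""Shared raster grid definition and named layer stacks.

Everything downstream of occurrence cleaning lives on one :class:`RasterGrid`
— a regular lon/lat (WGS84) grid with square cells, addressed GDAL-style from
the north-west corner. Layers are plain float64 arrays carrying ``nan`` in
invalid cells; a stack's validity mask is shared by all layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = ["RasterGrid", "RasterStack"]

#: metres per degree of latitude (spherical Earth, WGS84 mean radius)
M_PER_DEG = 111_320.0


@dataclass(frozen=True)
class RasterGrid:
    """Regular geographic grid: extent, resolution, CRS and nodata sentinel.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; row 0 is the northernmost row.
    cell_size
        Square cell edge, in degrees.
    x_min
        Western edge (longitude of the west side of column 0).
    y_max
        Northern edge (latitude of the north side of row 0).
    """

    n_rows: int
    n_cols: int
    cell_size: float
    x_min: float = 0.0
    y_max: float = 0.0
    crs: str = "EPSG:4326"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_max - self.n_rows * self.cell_size

    @property
    def mid_latitude(self) -> float:
        return 0.5 * (self.y_min + self.y_max)

    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of cell centers, each shaped ``(n_rows, n_cols)``."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point; may fall off-grid."""
        col = np.floor((np.asarray(lon, float) - self.x_min) / self.cell_size).astype(int)
        row = np.floor((self.y_max - np.asarray(lat, float)) / self.cell_size).astype(int)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.cell_index(lon, lat)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        lon = self.x_min + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.y_max - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def same_frame(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.x_min, other.x_min)
            and np.isclose(self.y_max, other.y_max)
            and self.crs == other.crs
        )


class RasterStack:
    """An ordered set of named layers sharing one grid and one validity mask.

    Layers are stored as float64 arrays with ``nan`` outside the mask; the
    mask is the intersection of per-layer validity and any explicit mask
    applied (e.g. by range clipping).
    """

    def __init__(
        self,
        grid: RasterGrid,
        layers: Mapping[str, np.ndarray] | None = None,
        mask: np.ndarray | None = None,
    ) -> None:
        self.grid = grid
        self._layers: dict[str, np.ndarray] = {}
        self.mask = np.ones(grid.shape, dtype=bool) if mask is None else mask.astype(bool).copy()
        if self.mask.shape != grid.shape:
            raise ValueError("mask shape does not match grid")
        if layers:
            for name, arr in layers.items():
                self.add_layer(name, arr)

    # -- container protocol -------------------------------------------------
    @property
    def layer_names(self) -> list[str]:
        return list(self._layers)

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __getitem__(self, name: str) -> np.ndarray:
        return self._layers[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def add_layer(self, name: str, values: np.ndarray) -> None:
        arr = np.asarray(values, dtype=float).copy()
        if arr.shape != self.grid.shape:
            raise ValueError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")
        self.mask &= np.isfinite(arr)
        self._layers[name] = arr
        self._apply_mask()

    def _apply_mask(self) -> None:
        for arr in self._layers.values():
            arr[~self.mask] = np.nan

    def set_mask(self, mask: np.ndarray) -> None:
        self.mask &= mask.astype(bool)
        self._apply_mask()

    # -- views --------------------------------------------------------------
    def subset(self, names: Iterable[str]) -> "RasterStack":
        names = list(names)
        missing = [n for n in names if n not in self._layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return RasterStack(self.grid, {n: self._layers[n] for n in names}, self.mask)

    def copy(self) -> "RasterStack":
        return RasterStack(self.grid, {n: a for n, a in self._layers.items()}, self.mask)

    def table(self, names: Iterable[str] | None = None) -> "pd.DataFrame":
        """Valid-cell values as a DataFrame (one row per valid cell, in row-major order)."""
        import pandas as pd

        names = self.layer_names if names is None else list(names)
        return pd.DataFrame({n: self._layers[n][self.mask] for n in names})

    def values_at(self, lon, lat, names: Iterable[str] | None = None) -> "pd.DataFrame":
        """Layer values at the cells containing the given points."""
        import pandas as pd

        names = self.layer_names if names is None else list(names)
        row, col = self.grid.cell_index(lon, lat)
        inside = (row >= 0) & (row < self.grid.n_rows) & (col >= 0) & (col < self.grid.n_cols)
        if not np.all(inside):
            raise ValueError("points fall outside the grid extent")
        return pd.DataFrame({n: self._layers[n][row, col] for n in names})

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())
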