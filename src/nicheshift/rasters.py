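"""Raster-stack operations: range masking, terrain ruggedness, predictor pruning,
and grid harmonization.

The study frame is lon/lat (WGS84); buffering distances are given in metres
and applied in a local equirectangular metric frame centred on the polygon,
which is accurate to well under a cell at the ~1 km scales involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shp_transform
from shapely.prepared import prep
from shapely.validation import make_valid

from .grid import M_PER_DEG, RasterGrid, RasterStack

__all__ = [
    "RangeArea",
    "buffer_polygon_m",
    "polygon_mask",
    "buffer_and_mask",
    "compute_tri",
    "select_uncorrelated",
    "resample_to_grid",
]


@dataclass
class RangeArea:
    """A species' range polygon plus the buffering distance applied to it.

    ``buffer_m`` is metres: dispersal-scaled context around the mapped range
    (e.g. 1500 m for a wide-ranging snake, 36 m for a sedentary rodent).
    """

    species: str
    polygon: BaseGeometry
    buffer_m: float = 0.0

    def __post_init__(self) -> None:
        if self.buffer_m < 0:
            raise ValueError("buffer_m must be >= 0")
        if not self.polygon.is_valid:
            self.polygon = make_valid(self.polygon)

    def buffered(self) -> BaseGeometry:
        return buffer_polygon_m(self.polygon, self.buffer_m)


def buffer_polygon_m(polygon: BaseGeometry, buffer_m: float) -> BaseGeometry:
    """Buffer a lon/lat polygon by a metric distance.

    The polygon is projected to a local equirectangular frame (x scaled by
    cos of its mid-latitude), buffered in metres, and projected back.
    """
    if buffer_m == 0:
        return polygon
    lat0 = polygon.centroid.y
    kx = M_PER_DEG * np.cos(np.radians(lat0))
    ky = M_PER_DEG
    fwd = shp_transform(lambda x, y: (np.asarray(x) * kx, np.asarray(y) * ky), polygon)
    buf = fwd.buffer(buffer_m)
    out = shp_transform(lambda x, y: (np.asarray(x) / kx, np.asarray(y) / ky), buf)
    return make_valid(out) if not out.is_valid else out


def polygon_mask(grid: RasterGrid, polygon: BaseGeometry) -> np.ndarray:
    """Boolean cell mask: True where the cell center lies inside the polygon."""
    gx, gy = grid.center_mesh()
    prepared = prep(polygon)
    from shapely import points as shp_points

    pts = shp_points(gx.ravel(), gy.ravel())
    return np.fromiter(
        (prepared.contains(p) for p in pts), dtype=bool, count=pts.size
    ).reshape(grid.shape)


def buffer_and_mask(stack: RasterStack, range_: RangeArea) -> RasterStack:
    """Mask every layer to the metric-buffered range polygon.

    Cells whose centers fall outside the buffered polygon become nodata;
    cells inside keep their values bit-for-bit.
    """
    inside = polygon_mask(stack.grid, range_.buffered())
    if not np.any(inside & stack.mask):
        raise ValueError(
            f"range polygon for {range_.species!r} does not intersect any valid cell"
        )
    out = stack.copy()
    out.set_mask(inside)
    return out


def compute_tri(elevation: np.ndarray) -> np.ndarray:
    """Terrain ruggedness index: sqrt of summed squared elevation differences
    to the 8 neighbours (Riley et al. definition).

    Edge cells use the neighbours that exist; nodata (nan) cells yield nodata
    and are skipped as neighbours.
    """
    z = np.asarray(elevation, dtype=float)
    valid = np.isfinite(z)
    z0 = np.where(valid, z, 0.0)
    acc = np.zeros_like(z0)
    pad_z = np.pad(z0, 1)
    pad_v = np.pad(valid, 1)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            zn = pad_z[1 + di : 1 + di + z.shape[0], 1 + dj : 1 + dj + z.shape[1]]
            vn = pad_v[1 + di : 1 + di + z.shape[0], 1 + dj : 1 + dj + z.shape[1]]
            acc += vn * (zn - z0) ** 2
    tri = np.sqrt(acc)
    tri[~valid] = np.nan
    return tri


def select_uncorrelated(
    stack: RasterStack,
    threshold: float = 0.8,
    priority: list[str] | None = None,
) -> RasterStack:
    """Greedy correlation pruning: drop the lower-priority member of every
    layer pair with |Pearson r| >= threshold, scanning pairs by descending |r|.

    ``priority`` is a total order over layer names (earlier = kept in a tie
    with a later one); it defaults to stack order. Pearson r is computed over
    jointly valid cells. Zero-variance layers are excluded with a warning.
    """
    if len(stack) < 2:
        raise ValueError("need at least two layers to prune")
    priority = list(priority) if priority is not None else stack.layer_names
    unknown = [n for n in stack.layer_names if n not in priority]
    if unknown:
        raise ValueError(f"priority list does not cover layers: {unknown}")
    rank = {name: i for i, name in enumerate(priority)}

    tbl = stack.table()
    keep = []
    for name in stack.layer_names:
        if np.nanstd(tbl[name].to_numpy()) == 0:
            warnings.warn(f"layer {name!r} has zero variance; excluded from pruning")
        else:
            keep.append(name)
    corr = tbl[keep].corr().to_numpy()

    pairs = [
        (abs(corr[i, j]), keep[i], keep[j])
        for i in range(len(keep))
        for j in range(i + 1, len(keep))
    ]
    pairs.sort(key=lambda t: (-t[0], min(rank[t[1]], rank[t[2]])))
    alive = set(keep)
    for r, a, b in pairs:
        if r < threshold:
            break
        if a in alive and b in alive:
            alive.discard(a if rank[a] > rank[b] else b)
    survivors = [n for n in stack.layer_names if n in alive]
    return stack.subset(survivors)


def resample_to_grid(
    stack: RasterStack, target: RasterGrid, method: str = "bilinear"
) -> RasterStack:
    """Resample every layer onto ``target`` (nearest or bilinear).

    Bilinear interpolation runs on nodata-aware values: a target cell is
    nodata when its nearest source cell is invalid. Identical grids pass
    through bit-identically.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    src = stack.grid
    if src.crs != target.crs:
        raise ValueError("CRS mismatch between source and target grids")
    if src.same_frame(target):
        return stack.copy()
    if (
        target.x_min >= src.x_max
        or target.x_max <= src.x_min
        or target.y_min >= src.y_max
        or target.y_max <= src.y_min
    ):
        raise ValueError("target grid extent is disjoint from the source")

    tx, ty = target.center_mesh()
    # fractional source indices of target cell centers
    col_f = (tx - src.x_min) / src.cell_size - 0.5
    row_f = (src.y_max - ty) / src.cell_size - 0.5
    nearest = (
        np.clip(np.round(row_f), 0, src.n_rows - 1).astype(int),
        np.clip(np.round(col_f), 0, src.n_cols - 1).astype(int),
    )
    out = RasterStack(target)
    for name in stack.layer_names:
        arr = stack[name]
        if method == "nearest":
            vals = arr[nearest]
        else:
            # nodata-aware bilinear: interpolate value*weight and weight
            # separately so invalid neighbours do not bleed zeros in
            good = np.isfinite(arr)
            filled = np.where(good, arr, 0.0)
            num = ndimage.map_coordinates(filled, [row_f, col_f], order=1, mode="nearest")
            den = ndimage.map_coordinates(
                good.astype(float), [row_f, col_f], order=1, mode="nearest"
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(den > 0.5, num / den, np.nan)
            vals = np.where(good[nearest], vals, np.nan)
        out.add_layer(name, vals)
    return out
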