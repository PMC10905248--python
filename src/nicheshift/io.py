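"""Plain-text IO: ESRI ASCII grids, GeoJSON polygons, occurrence CSV, model JSON.

All on-disk formats are text so a run directory can be diffed and versioned.
ASCII grids carry the full grid definition in their header; multi-layer stacks
are written one file per layer plus a small JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid import RasterGrid, RasterStack

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_stack",
    "read_stack",
    "write_geojson",
    "read_geojson",
    "read_occurrences",
    "write_occurrences",
]

OCC_COLUMNS = ["species", "decimalLongitude", "decimalLatitude", "taxonRank"]


def write_ascii_grid(path: str | Path, values: np.ndarray, grid: RasterGrid) -> None:
    """Write one layer as an ESRI ASCII grid; nan becomes the grid's nodata."""
    arr = np.asarray(values, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    out = np.where(np.isfinite(arr), arr, grid.nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {float(grid.x_min)!r}\n"
        f"yllcorner {float(grid.y_min)!r}\n"
        f"cellsize {float(grid.cell_size)!r}\n"
        f"NODATA_value {float(grid.nodata)!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, RasterGrid]:
    """Read an ESRI ASCII grid; nodata cells come back as nan."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", -9999.0)
    grid = RasterGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=header["cellsize"],
        x_min=header["xllcorner"],
        y_max=header["yllcorner"] + n_rows * header["cellsize"],
        nodata=nodata,
    )
    data[data == nodata] = np.nan
    return data, grid


def write_stack(directory: str | Path, stack: RasterStack) -> Path:
    """Write every layer as ``<name>.asc`` plus a ``stack.json`` manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"crs": stack.grid.crs, "layers": {}}
    for name in stack.layer_names:
        fname = f"{name}.asc"
        write_ascii_grid(directory / fname, stack[name], stack.grid)
        manifest["layers"][name] = fname
    (directory / "stack.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return directory


def read_stack(directory: str | Path) -> RasterStack:
    directory = Path(directory)
    manifest = json.loads((directory / "stack.json").read_text())
    stack: RasterStack | None = None
    for name, fname in manifest["layers"].items():
        data, grid = read_ascii_grid(directory / fname)
        if stack is None:
            stack = RasterStack(grid)
        stack.add_layer(name, data)
    if stack is None:
        raise ValueError(f"empty stack manifest in {directory}")
    return stack


def write_geojson(path: str | Path, geoms: Mapping[str, BaseGeometry]) -> None:
    features = [
        {"type": "Feature", "properties": {"name": name}, "geometry": mapping(geom)}
        for name, geom in geoms.items()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
    )


def read_geojson(path: str | Path) -> dict[str, BaseGeometry]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        return {
            f["properties"].get("name", str(i)): shape(f["geometry"])
            for i, f in enumerate(doc["features"])
        }
    return {"0": shape(doc.get("geometry", doc))}


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("decimalLongitude", "decimalLatitude") if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence table lacks columns: {missing}")
    return df


def write_occurrences(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)
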