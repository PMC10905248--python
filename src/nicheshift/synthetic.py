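"""Synthetic study system with known ground truth.

Generates everything the desk-scale analysis needs in place of downloaded
occurrence snapshots and climate rasters: correlated environmental fields,
a known log-linear "true niche" per species, spatially biased presence
samples (with injected dirty records to exercise cleaning), range polygons,
and climate-perturbation scenario stacks with a known direction of change.

Random fields are white noise convolved with a Gaussian kernel and then
standardized — cheap, controllable spatial autocorrelation. Correlated pairs
are built by mixing B = rho*A + sqrt(1-rho^2)*E with E empirically
orthogonalized against A, so the realized Pearson r equals rho exactly.
None of this emulates real bioclimatic covariance or GCM physics; it gives
the pipeline inputs whose statistical structure (collinearity, sampling bias,
directional scenario shifts) matches the study's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import MultiPoint

from .grid import RasterGrid, RasterStack
from .maxent import SuitabilityMap
from .occurrences import LAT, LON, BiasSurface
from .rasters import RangeArea

__all__ = [
    "TruthSpec",
    "ScenarioDelta",
    "make_env_stack",
    "make_bias_field",
    "make_truth_and_sample",
    "make_scenario",
    "make_range_polygon",
]


@dataclass
class TruthSpec:
    """The true (generator-known) niche: log-linear weights on standardized layers."""

    layer_names: list[str]
    true_coefficients: dict[str, float]
    bias_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [n for n in self.true_coefficients if n not in self.layer_names]
        if unknown:
            raise ValueError(f"coefficients on layers not in layer_names: {unknown}")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")


@dataclass
class ScenarioDelta:
    """Cell-wise perturbation x -> x*factor + shift per listed layer.

    Layers absent from ``layer_deltas`` are held constant — the static-terrain
    convention (elevation, ruggedness, soil do not change between periods).
    """

    layer_deltas: dict[str, tuple[float, float]]  # name -> (shift, factor)
    label: str = "scenario"

    def __post_init__(self) -> None:
        for name, (_, factor) in self.layer_deltas.items():
            if factor <= 0:
                raise ValueError(f"multiplicative factor for {name!r} must be > 0")


def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], sigma: float
) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def _orthogonalize(e: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Residual of e against a, restandardized (empirical orthogonality)."""
    r = e - (e.ravel() @ a.ravel()) / (a.ravel() @ a.ravel()) * a
    return (r - r.mean()) / r.std()


def make_env_stack(
    grid: RasterGrid,
    n_layers: int,
    pairwise_corr: float = 0.0,
    seed: int = 0,
    smooth_sigma: float = 1.5,
    prefix: str = "env",
) -> RasterStack:
    """Generate ``n_layers`` smoothed random fields plus a latitudinal gradient.

    With ``pairwise_corr`` rho > 0, consecutive layer pairs (1,2), (3,4), ...
    are mixed so each pair's realized Pearson correlation is exactly rho;
    unpaired layers stay mutually independent by construction. Deterministic
    for a fixed seed.
    """
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    if grid.n_rows < 20 or grid.n_cols < 20:
        raise ValueError("grid must be at least 20x20 cells")
    if not 0.0 <= pairwise_corr < 1.0:
        raise ValueError("pairwise_corr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    fields = [_smooth_field(rng, grid.shape, smooth_sigma) for _ in range(n_layers)]
    if pairwise_corr > 0:
        rho = pairwise_corr
        for i in range(0, n_layers - 1, 2):
            a = fields[i]
            e = _orthogonalize(fields[i + 1], a)
            fields[i + 1] = rho * a + np.sqrt(1 - rho**2) * e
    stack = RasterStack(grid)
    width = max(2, len(str(n_layers)))
    for j, f in enumerate(fields, start=1):
        stack.add_layer(f"{prefix}{j:0{width}d}", f)
    _, lat = grid.center_mesh()
    gradient = (lat - lat.mean()) / lat.std()
    stack.add_layer("lat_gradient", gradient)
    return stack


def make_bias_field(grid: RasterGrid, strength: float, seed: int = 0) -> BiasSurface:
    """A smooth multiplicative sampling-effort field, exp(strength * field).

    strength 0 gives a uniform surface (no bias)."""
    rng = np.random.default_rng(seed)
    f = _smooth_field(rng, grid.shape, sigma=3.0)
    return BiasSurface(grid, np.exp(strength * f))


def _standardized_table(stack: RasterStack, names: list[str]) -> np.ndarray:
    tbl = stack.table(names).to_numpy()
    mu = tbl.mean(axis=0)
    sd = tbl.std(axis=0)
    sd[sd == 0] = 1.0
    return (tbl - mu) / sd


def true_suitability(stack: RasterStack, truth: TruthSpec) -> SuitabilityMap:
    """s(x) proportional to exp(sum_j lambda_j z_j(x)) over valid cells, sum 1."""
    if stack.n_valid == 0:
        raise ValueError("stack has no valid cells")
    names = [n for n in truth.layer_names if n in truth.true_coefficients]
    missing = [n for n in truth.layer_names if n not in stack]
    if missing:
        raise ValueError(f"truth references layers missing from stack: {missing}")
    vals = np.full(stack.grid.shape, np.nan)
    if names:
        z = _standardized_table(stack, names)
        lam = np.array([truth.true_coefficients[n] for n in names])
        eta = z @ lam
    else:
        eta = np.zeros(stack.n_valid)
    eta -= eta.max()
    s = np.exp(eta)
    vals[stack.mask] = s / s.sum()
    return SuitabilityMap(stack.grid, vals, "raw")


def make_truth_and_sample(
    stack: RasterStack,
    truth: TruthSpec,
    n_presence: int,
    bias: BiasSurface | None = None,
    species: str = "species_a",
    dirty_fraction: float = 0.05,
) -> tuple[SuitabilityMap, pd.DataFrame]:
    """True suitability surface plus a biased presence sample.

    Presence cells are multinomial with probability proportional to
    s(x)*bias(x) (bias identically 1 when None); each point is placed
    uniformly inside its cell. A ``dirty_fraction`` of extra rows — exact
    duplicates, missing-coordinate rows, and subspecies-tagged rows — is
    appended so the cleaning filters have work to do.
    """
    if n_presence < 1:
        raise ValueError("n_presence must be >= 1")
    s_map = true_suitability(stack, truth)
    rng = np.random.default_rng(truth.seed)
    g = stack.grid
    w = np.where(stack.mask, s_map.values, 0.0)
    if bias is not None:
        if not bias.grid.same_frame(g):
            raise ValueError("bias surface grid differs from the stack grid")
        w = w * bias.weights
    p = (w / w.sum()).ravel()
    counts = rng.multinomial(n_presence, p)
    rows, cols = np.unravel_index(
        np.repeat(np.arange(p.size), counts), g.shape
    )
    lon = g.x_min + (cols + rng.random(n_presence)) * g.cell_size
    lat = g.y_max - (rows + rng.random(n_presence)) * g.cell_size
    occ = pd.DataFrame(
        {"species": species, LON: lon, LAT: lat, "taxonRank": "species"}
    )
    n_dirty = int(round(dirty_fraction * n_presence))
    dirty_rows = []
    for i in range(n_dirty):
        kind = i % 3
        if kind == 0:  # exact duplicate of an existing record
            dirty_rows.append(occ.iloc[int(rng.integers(n_presence))].to_dict())
        elif kind == 1:  # missing coordinate
            dirty_rows.append(
                {"species": species, LON: np.nan, LAT: np.nan, "taxonRank": "species"}
            )
        else:  # subspecies-tagged record
            src = occ.iloc[int(rng.integers(n_presence))].to_dict()
            src["taxonRank"] = "subspecies"
            dirty_rows.append(src)
    if dirty_rows:
        occ = pd.concat([occ, pd.DataFrame(dirty_rows)], ignore_index=True)
    return s_map, occ


def make_scenario(stack: RasterStack, delta: ScenarioDelta) -> RasterStack:
    """Apply a scenario perturbation; unlisted layers pass through bit-identically."""
    unknown = [n for n in delta.layer_deltas if n not in stack]
    if unknown:
        raise ValueError(f"delta references layers missing from stack: {unknown}")
    out = stack.copy()
    for name, (shift, factor) in delta.layer_deltas.items():
        arr = out[name]
        arr[out.mask] = arr[out.mask] * factor + shift
    return out


def make_range_polygon(
    s_map: SuitabilityMap,
    species: str,
    quantile: float = 0.25,
    buffer_m: float = 0.0,
) -> RangeArea:
    """A deterministic range polygon: convex hull of cell centers whose true
    suitability exceeds the given quantile, dilated by one cell so boundary
    cell centers fall inside."""
    g = s_map.grid
    vals = s_map.values[s_map.mask]
    cut = np.quantile(vals, quantile)
    gx, gy = g.center_mesh()
    sel = s_map.mask & (s_map.values >= cut)
    hull = MultiPoint(list(zip(gx[sel], gy[sel]))).convex_hull
    return RangeArea(species, hull.buffer(g.cell_size), buffer_m=buffer_m)
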