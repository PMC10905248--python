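"""Configuration-driven orchestration of the full two-species analysis.

One :class:`RunConfig` drives both species through identical stages:

    generate -> clean -> thin -> bias -> background -> mask to range ->
    prune correlated layers -> select rm (AICc) -> k-fold cross-validation ->
    current + scenario projection -> GCM averaging -> niche overlap ->
    vulnerability assessment

A master seed fans out to named per-stage sub-seeds; species-level sub-seeds
are keyed by the species name (not list position) so relabelling the pair
swaps report rows without changing any draw. All outputs are text files under
a run directory with a JSON manifest; a repeated run under the same config is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .grid import RasterGrid, RasterStack
from .maxent import (
    MaxentModel,
    SuitabilityMap,
    cross_validate,
    fit_maxent,
    predict_map_ensemble,
    select_rm,
    variable_importance,
)
from .niche_metrics import (
    intersect_ranges,
    normalize_surface,
    schoener_d,
    vulnerability_report,
    warren_i,
)
from .occurrences import (
    LAT,
    LON,
    BiasSurface,
    build_bias_surface,
    clean_records,
    sample_background,
    thin_by_grid,
)
from .projection import ScenarioSet, average_gcms, project_scenario
from .rasters import (
    RangeArea,
    buffer_and_mask,
    compute_tri,
    polygon_mask,
    select_uncorrelated,
)
from .synthetic import (
    ScenarioDelta,
    TruthSpec,
    make_bias_field,
    make_env_stack,
    make_range_polygon,
    make_scenario,
    make_truth_and_sample,
)

logger = logging.getLogger("nicheshift")

__all__ = ["SpeciesConfig", "ScenarioConfig", "RunConfig", "run_pipeline", "render_report"]


def stage_seed(master_seed: int, tag: str) -> int:
    """Deterministic per-stage sub-seed: master seed mixed with a stage tag."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0]) % (2**31)


@dataclass
class SpeciesConfig:
    """Study conditions for one species of the pair."""

    name: str
    true_coefficients: dict[str, float]
    n_presence: int = 500
    buffer_m: float = 1500.0
    range_quantile: float = 0.25
    bias_strength: float = 0.5
    seed_tag: str | None = None  # defaults to the species name

    @property
    def tag(self) -> str:
        return self.seed_tag if self.seed_tag is not None else self.name


@dataclass
class ScenarioConfig:
    """A labelled climate perturbation applied through three GCM variants.

    ``deltas`` maps layer name -> (additive shift, multiplicative factor) in
    the layer's own units; per-GCM stacks scale the shift by ``gcm_scale`` to
    emulate between-GCM spread. ``past=True`` marks a paleo period whose
    vulnerability entry reads past-to-current.
    """

    label: str
    deltas: dict[str, tuple[float, float]]
    past: bool = False
    gcm_names: tuple[str, ...] = ("gcm1", "gcm2", "gcm3")
    gcm_scale: tuple[float, ...] = (0.8, 1.0, 1.2)

    def gcm_delta(self, i: int) -> ScenarioDelta:
        s = self.gcm_scale[i]
        return ScenarioDelta(
            {k: (shift * s, 1.0 + (factor - 1.0) * s) for k, (shift, factor) in self.deltas.items()},
            label=f"{self.label}:{self.gcm_names[i]}",
        )


@dataclass
class RunConfig:
    """Full study configuration with desk-scale synthetic defaults."""

    # grid (Great Plains-like frame)
    n_rows: int = 50
    n_cols: int = 50
    cell_size: float = 0.05
    x_min: float = -105.0
    y_max: float = 42.0
    # synthetic environment
    n_climate_layers: int = 8
    pairwise_corr: float = 0.9
    smooth_sigma: float = 1.5
    dirty_fraction: float = 0.05
    # occurrence preparation
    thin_cell_km: float = 5.0
    background_n: int = 10_000
    bias_smooth_cells: float = 1.0
    # predictors and model
    corr_threshold: float = 0.8
    priority: list[str] | None = None  # default: stack order
    feature_classes: tuple[str, ...] = ("linear", "quadratic", "hinge")
    n_hinge_knots: int = 8
    rm_grid: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    k_folds: int = 5
    # output scales
    overlap_scale: str = "raw"
    h_scale: str = "cloglog"
    jackknife: bool = False
    master_seed: int = 42
    species: list[SpeciesConfig] = field(default_factory=list)
    scenarios: list[ScenarioConfig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species:
            self.species = default_species()
        if not self.scenarios:
            self.scenarios = default_scenarios()

    @property
    def grid(self) -> RasterGrid:
        return RasterGrid(self.n_rows, self.n_cols, self.cell_size, self.x_min, self.y_max)

    # -- (de)serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        doc["species"] = [SpeciesConfig(**s) for s in doc.get("species", [])]
        scen = []
        for s in doc.get("scenarios", []):
            s = dict(s)
            s["deltas"] = {k: tuple(v) for k, v in s["deltas"].items()}
            for key in ("gcm_names", "gcm_scale"):
                if key in s:
                    s[key] = tuple(s[key])
            scen.append(ScenarioConfig(**s))
        doc["scenarios"] = scen
        for key in ("feature_classes", "rm_grid"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def default_species() -> list[SpeciesConfig]:
    """The default pair: a temperature-limited ectotherm analogue (cool-adapted
    predator, moisture-dependent) and an endotherm analogue tied to substrate
    and a moisture-like field but indifferent to temperature."""
    return [
        SpeciesConfig(
            name="ectotherm_predator",
            true_coefficients={"env01": -2.0, "env03": 1.5},
            buffer_m=1500.0,
        ),
        SpeciesConfig(
            name="endotherm_prey",
            true_coefficients={"env05": 1.5, "sand": 1.0},
            buffer_m=36.0,
        ),
    ]


def default_scenarios() -> list[ScenarioConfig]:
    """Warming-family futures (the temperature-like layer env01 rises, the
    moisture-like layer env05 rises mildly) plus two paleo periods: a cool,
    dry glacial maximum and a mildly different mid-period."""
    return [
        ScenarioConfig("RCP2.6-like", {"env01": (0.5, 1.0), "env05": (0.17, 1.0)}),
        ScenarioConfig("RCP4.5-like", {"env01": (1.0, 1.0), "env05": (0.33, 1.0)}),
        ScenarioConfig("RCP8.5-like", {"env01": (1.5, 1.0), "env05": (0.5, 1.0)}),
        ScenarioConfig(
            "MH-like", {"env01": (-0.2, 1.0), "env03": (-0.2, 1.0)}, past=True
        ),
        ScenarioConfig(
            "LGM-like",
            {"env01": (-1.0, 1.0), "env03": (-2.0, 1.0), "env05": (-2.0, 1.0)},
            past=True,
        ),
    ]


@dataclass
class SpeciesResult:
    name: str
    stack: RasterStack
    range_area: RangeArea
    occurrences: pd.DataFrame
    best_rm: float
    rm_table: pd.DataFrame
    fold_aucs: list[float]
    mean_auc: float
    fold_models: list[MaxentModel]
    full_model: MaxentModel
    importance: pd.DataFrame
    current_h: SuitabilityMap  # on the H scale (default cloglog)
    current_overlap: SuitabilityMap  # on the overlap scale (default raw)
    scenario_maps: dict[str, SuitabilityMap]  # GCM-averaged, H scale


@dataclass
class PipelineResult:
    config: RunConfig
    species: dict[str, SpeciesResult]
    d_overlap: float
    i_overlap: float
    report: "pd.DataFrame"
    h_values: dict
    run_dir: Path | None


def _build_environment(config: RunConfig) -> RasterStack:
    grid = config.grid
    stack = make_env_stack(
        grid,
        config.n_climate_layers,
        pairwise_corr=config.pairwise_corr,
        seed=stage_seed(config.master_seed, "env"),
        smooth_sigma=config.smooth_sigma,
    )
    rng = np.random.default_rng(stage_seed(config.master_seed, "terrain"))
    from scipy import ndimage

    rough = ndimage.gaussian_filter(rng.standard_normal(grid.shape), 2.0, mode="reflect")
    elev = 1000.0 + 500.0 * (rough - rough.mean()) / rough.std()
    stack.add_layer("elev", elev)
    stack.add_layer("tri", compute_tri(elev))
    sandf = ndimage.gaussian_filter(rng.standard_normal(grid.shape), 2.0, mode="reflect")
    sand = np.clip(50.0 + 20.0 * (sandf - sandf.mean()) / sandf.std(), 0.0, 100.0)
    stack.add_layer("sand", sand)
    return stack


def _prepare_species(
    config: RunConfig, sp: SpeciesConfig, stack: RasterStack
) -> tuple[SuitabilityMap, pd.DataFrame, RangeArea]:
    truth = TruthSpec(
        layer_names=stack.layer_names,
        true_coefficients=sp.true_coefficients,
        bias_strength=sp.bias_strength,
        seed=stage_seed(config.master_seed, f"sample:{sp.tag}"),
    )
    bias = (
        make_bias_field(
            stack.grid, sp.bias_strength, seed=stage_seed(config.master_seed, "effort")
        )
        if sp.bias_strength > 0
        else None
    )
    s_true, occ_raw = make_truth_and_sample(
        stack,
        truth,
        sp.n_presence,
        bias=bias,
        species=sp.name,
        dirty_fraction=config.dirty_fraction,
    )
    range_area = make_range_polygon(
        s_true, sp.name, quantile=sp.range_quantile, buffer_m=sp.buffer_m
    )
    return s_true, occ_raw, range_area


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis for the configured species pair.

    Returns the in-memory results; when ``out_dir`` is given also writes maps
    (ASCII grids), tables (CSV/JSON), model files and a manifest there.
    """
    if len(config.species) != 2:
        raise ValueError("the pipeline analyses exactly two species")
    grid = config.grid
    logger.info("generating environment stack (%dx%d)", grid.n_rows, grid.n_cols)
    stack = _build_environment(config)

    # -- occurrences (generate, clean, thin) ---------------------------------
    prepared: dict[str, dict] = {}
    cleaned_pool = []
    for sp in config.species:
        s_true, occ_raw, range_area = _prepare_species(config, sp, stack)
        occ_clean = clean_records(occ_raw)
        occ_thin = thin_by_grid(
            occ_clean,
            grid,
            cell_km=config.thin_cell_km,
            seed=stage_seed(config.master_seed, f"thin:{sp.tag}"),
        )
        cleaned_pool.append(occ_clean)
        prepared[sp.name] = {
            "config": sp,
            "truth_map": s_true,
            "occ": occ_thin,
            "range": range_area,
        }
        logger.info(
            "%s: %d raw -> %d cleaned -> %d thinned records",
            sp.name, len(occ_raw), len(occ_clean), len(occ_thin),
        )

    # target-group sampling-effort surface from the pooled records
    target_group = pd.concat(cleaned_pool, ignore_index=True)
    effort = build_bias_surface(target_group, grid, smooth_cells=config.bias_smooth_cells)

    species_results: dict[str, SpeciesResult] = {}
    for sp in config.species:
        p = prepared[sp.name]
        masked = buffer_and_mask(stack, p["range"])
        pruned = select_uncorrelated(
            masked, threshold=config.corr_threshold, priority=config.priority
        )
        occ = p["occ"]
        inside = masked.grid.contains(occ[LON], occ[LAT])
        row, col = masked.grid.cell_index(occ[LON], occ[LAT])
        ok = inside.copy()
        ok[inside] = masked.mask[row[inside], col[inside]]
        occ = occ[ok].reset_index(drop=True)

        w = effort.weights * masked.mask
        bias = BiasSurface(grid, w)
        background = sample_background(
            bias, n=config.background_n,
            seed=stage_seed(config.master_seed, f"background:{sp.tag}"),
        )
        pres_env = pruned.values_at(occ[LON], occ[LAT])
        bg_env = pruned.values_at(background[LON], background[LAT])

        logger.info("%s: selecting rm over %s", sp.name, config.rm_grid)
        best_rm, rm_table = select_rm(
            pres_env, bg_env, list(config.rm_grid),
            classes=config.feature_classes, n_hinge_knots=config.n_hinge_knots,
        )
        cv = cross_validate(
            pres_env, bg_env, k=config.k_folds, rm=best_rm,
            classes=config.feature_classes, n_hinge_knots=config.n_hinge_knots,
            seed=stage_seed(config.master_seed, f"cv:{sp.tag}"),
        )
        full = fit_maxent(
            pres_env, bg_env, rm=best_rm,
            classes=config.feature_classes, n_hinge_knots=config.n_hinge_knots,
        )
        if config.jackknife:
            importance = variable_importance(full, pres_env, bg_env)
        else:
            importance = pd.DataFrame(
                {
                    "variable": list(full.contributions),
                    "percent_contribution": list(full.contributions.values()),
                }
            )
        importance = importance.sort_values(
            "percent_contribution", ascending=False
        ).reset_index(drop=True)

        current_h = predict_map_ensemble(cv.models, pruned, scale=config.h_scale)
        current_ov = predict_map_ensemble(cv.models, pruned, scale=config.overlap_scale)

        scenario_maps: dict[str, SuitabilityMap] = {}
        for scen in config.scenarios:
            gcm_stacks = {
                scen.gcm_names[i]: make_scenario(masked, scen.gcm_delta(i))
                for i in range(len(scen.gcm_names))
            }
            per_gcm = project_scenario(
                cv.models, ScenarioSet(scen.label, gcm_stacks), scale=config.h_scale
            )
            scenario_maps[scen.label] = average_gcms(per_gcm)

        species_results[sp.name] = SpeciesResult(
            name=sp.name,
            stack=pruned,
            range_area=p["range"],
            occurrences=occ,
            best_rm=best_rm,
            rm_table=rm_table,
            fold_aucs=cv.fold_aucs,
            mean_auc=cv.mean_auc,
            fold_models=cv.models,
            full_model=full,
            importance=importance,
            current_h=current_h,
            current_overlap=current_ov,
            scenario_maps=scenario_maps,
        )

    # -- overlap metrics ------------------------------------------------------
    name_a, name_b = (sp.name for sp in config.species)
    res_a, res_b = species_results[name_a], species_results[name_b]
    shared = res_a.current_overlap.mask & res_b.current_overlap.mask
    pa = normalize_surface(res_a.current_overlap, shared)
    pb = normalize_surface(res_b.current_overlap, shared)
    d_val = schoener_d(pa, pb)
    i_val = warren_i(pa, pb)

    # -- vulnerability assessment ---------------------------------------------
    inter_poly = intersect_ranges(res_a.range_area, res_b.range_area)
    overlap_mask = polygon_mask(grid, inter_poly) if not inter_poly.is_empty else np.zeros(grid.shape, bool)
    report = vulnerability_report(
        {name_a: res_a.current_h, name_b: res_b.current_h},
        {
            scen.label: {
                name_a: res_a.scenario_maps[scen.label],
                name_b: res_b.scenario_maps[scen.label],
            }
            for scen in config.scenarios
        },
        overlap_mask,
        past_labels={s.label for s in config.scenarios if s.past},
    )

    result = PipelineResult(
        config=config,
        species=species_results,
        d_overlap=d_val,
        i_overlap=i_val,
        report=report.changes,
        h_values=report.h_values,
        run_dir=None,
    )
    if out_dir is not None:
        result.run_dir = _write_outputs(Path(out_dir), result, report, inter_poly)
    return result


def _write_outputs(out_dir: Path, result: PipelineResult, report, inter_poly) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    for name, res in result.species.items():
        nio.write_ascii_grid(out_dir / f"current_{name}_{cfg.h_scale}.asc",
                             res.current_h.values, res.current_h.grid)
        nio.write_ascii_grid(out_dir / f"current_{name}_{cfg.overlap_scale}.asc",
                             res.current_overlap.values, res.current_overlap.grid)
        for label, m in res.scenario_maps.items():
            safe = label.replace("/", "_").replace(" ", "_")
            nio.write_ascii_grid(out_dir / f"scenario_{name}_{safe}.asc", m.values, m.grid)
            diff = m.values - res.current_h.values
            nio.write_ascii_grid(out_dir / f"diff_{name}_{safe}.asc", diff, m.grid)
        res.rm_table.to_csv(out_dir / f"rm_selection_{name}.csv", index=False)
        res.importance.to_csv(out_dir / f"importance_{name}.csv", index=False)
        res.full_model.save(out_dir / f"model_{name}.json")
        nio.write_occurrences(out_dir / f"occurrences_{name}.csv", res.occurrences)
    nio.write_geojson(
        out_dir / "ranges.geojson",
        {name: res.range_area.buffered() for name, res in result.species.items()}
        | ({"intersection": inter_poly} if not inter_poly.is_empty else {}),
    )
    auc = pd.DataFrame(
        {
            "species": list(result.species),
            "mean_auc": [r.mean_auc for r in result.species.values()],
            "best_rm": [r.best_rm for r in result.species.values()],
            "fold_aucs": [json.dumps(r.fold_aucs) for r in result.species.values()],
        }
    )
    auc.to_csv(out_dir / "auc.csv", index=False)
    result.report.to_csv(out_dir / "vulnerability.csv")
    (out_dir / "vulnerability.json").write_text(
        json.dumps(report.to_json_dict(), indent=1, sort_keys=True)
    )
    (out_dir / "overlap.json").write_text(
        json.dumps({"schoener_d": result.d_overlap, "warren_i": result.i_overlap},
                   indent=1, sort_keys=True)
    )
    import numpy as _np
    import pandas as _pd
    import scipy as _sp

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
        "versions": {
            "numpy": _np.__version__,
            "scipy": _sp.__version__,
            "pandas": _pd.__version__,
        },
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    return out_dir


def render_report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run directory."""
    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise FileNotFoundError(f"{run_dir} is not a completed run (no manifest.json)")
    lines = []
    auc_path = run_dir / "auc.csv"
    if auc_path.exists():
        auc = pd.read_csv(auc_path)
        lines.append("Model evaluation (5-fold cross-validation)")
        for _, r in auc.iterrows():
            lines.append(f"  {r['species']}: mean AUC = {r['mean_auc']:.3f} (rm = {r['best_rm']})")
    ov_path = run_dir / "overlap.json"
    if ov_path.exists():
        ov = json.loads(ov_path.read_text())
        lines.append("Abiotic niche overlap")
        lines.append(f"  Schoener's D = {ov['schoener_d']:.3f}")
        lines.append(f"  Warren's I   = {ov['warren_i']:.3f}")
    vul_path = run_dir / "vulnerability.json"
    if vul_path.exists():
        doc = json.loads(vul_path.read_text())
        changes = doc["changes"]
        rows = list(changes)
        cols = list(next(iter(changes.values()), {}))
        if cols:
            lines.append("Vulnerability assessment (% change in summed suitability)")
            width = max(len(r) for r in rows) + 2
            lines.append("  " + " " * width + "  ".join(f"{c:>12}" for c in cols))
            for r in rows:
                vals = "  ".join(f"{changes[r][c]:>11.2f}%" for c in cols)
                lines.append(f"  {r:<{width}}{vals}")
    else:
        lines.append("No scenario projections in this run (current-only diagnostics).")
    return "\n".join(lines) + "\n"
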