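"""Configuration-driven orchestration of the full mapping workflow.

Stages, in order: align inputs to the analysis grid -> DN-to-radiance ->
masked min-max normalization -> vegetation maximum composite -> HSI ->
per-class road KDE -> bandwidth sweep -> PCA class weights -> composite
RND -> zone-level power-law fit -> RNAHSI -> linear calibration ->
total-population correction -> disaggregation -> density -> accuracy
assessment.  Every run writes a manifest with the config hash and file
checksums; identical config + inputs give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import __version__
from .assess import AccuracyReport, residual_report
from .grid import Grid, GridSpec, align_stack, dn_to_radiance, max_composite, minmax_normalize
from .gtiff import read_geotiff, write_geotiff
from .indices import PowerLawFit, compute_hsi, compute_rnahsi, fit_power_law
from .kde import (
    BandwidthSweep,
    ClassWeights,
    bandwidth_sweep,
    composite_rnd,
    line_kde,
    pca_class_weights,
    zonal_class_sums,
)
from .popmap import LinearFit, disaggregate, fit_linear_calibration, to_density, zonal_sum
from .vectors import RoadNetwork, ZoneSet, read_census_csv, read_roads_geojson, read_zones_geojson

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline", "run_from_data"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


class InputPaths(BaseModel):
    ntl: Path
    evi: list[Path]
    roads: Path
    zones: Path
    census: Optional[Path] = None


class PipelineConfig(BaseModel):
    """Validated pipeline settings with method-matching defaults."""

    inputs: InputPaths
    output_dir: Path
    cell_size: float = 100.0
    radiance_exponent: float = 1.5
    evi_clamp: bool = True
    hsi_eps: float = 1e-9
    bandwidths: Optional[list[float]] = Field(
        default_factory=lambda: [float(b) for b in range(100, 5100, 100)]
    )
    chosen_bandwidth: float = 3000.0
    bandwidth_choice: Literal["default", "max_mean_r"] = "default"
    kde_method: Literal["direct", "fft"] = "direct"
    kde_spacing: Optional[float] = None
    index: Literal["rnahsi", "hsi"] = "rnahsi"
    mode: Literal["regression", "proportional", "proportional_by_zone"] = "regression"
    seed: int = 0

    @field_validator("cell_size", "chosen_bandwidth", "radiance_exponent")
    @classmethod
    def _positive(cls, v, info):
        if not v > 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v

    @field_validator("bandwidths")
    @classmethod
    def _bandwidths_ok(cls, v):
        if v is not None:
            if len(v) < 2:
                raise ValueError("bandwidths must list at least 2 values (or be null)")
            if any(b <= 0 for b in v):
                raise ValueError(f"bandwidths must be positive, got {v}")
        return v

    def config_hash(self) -> str:
        payload = self.model_dump_json(exclude={"output_dir"}).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(path: str | Path) -> PipelineConfig:
    """Load + validate a YAML config, with a readable error list."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise PipelineError("config", f"{path}: expected a mapping at top level")
    try:
        cfg = PipelineConfig(**raw)
    except ValidationError as exc:
        lines = [
            f"  - {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise PipelineError(
            "config", f"{path} is invalid:\n" + "\n".join(lines)
        ) from None
    for name, p in [
        ("inputs.ntl", cfg.inputs.ntl),
        ("inputs.roads", cfg.inputs.roads),
        ("inputs.zones", cfg.inputs.zones),
        *[(f"inputs.evi[{i}]", p) for i, p in enumerate(cfg.inputs.evi)],
        *([("inputs.census", cfg.inputs.census)] if cfg.inputs.census else []),
    ]:
        if not Path(p).exists():
            raise PipelineError("config", f"{name}: path does not exist: {p}")
    return cfg


@dataclass
class PipelineResult:
    """In-memory outputs of a run; file paths filled when written."""

    hsi: Grid
    rnahsi: Grid
    population: Grid
    density: Grid
    report: AccuracyReport
    rnd: Grid | None = None
    weights: ClassWeights | None = None
    power_fit: PowerLawFit | None = None
    sweep: BandwidthSweep | None = None
    linear_fit: LinearFit | None = None
    correction: float | None = None
    files: dict = field(default_factory=dict)


def _target_spec(ntl: Grid, cell_size: float) -> GridSpec:
    xmin, ymin, xmax, ymax = ntl.spec.bounds()
    rows = max(1, int(round((ymax - ymin) / cell_size)))
    cols = max(1, int(round((xmax - xmin) / cell_size)))
    return GridSpec((rows, cols), (xmin, ymax), cell_size, ntl.crs)


def run_from_data(
    ntl_dn: Grid,
    evi_layers: list[Grid],
    roads: RoadNetwork,
    zones: ZoneSet,
    config: PipelineConfig,
) -> PipelineResult:
    """Execute the workflow on in-memory inputs (no file I/O)."""

    def stage(name):
        log.info("stage: %s", name)
        return name

    t0 = time.perf_counter()
    name = stage("align")
    try:
        target = _target_spec(ntl_dn, config.cell_size)
        ntl_dn = align_stack([ntl_dn], target)[0]
        evi_layers = align_stack(evi_layers, target)
        labels = zones.label_grid(target)
        mask = labels >= 0
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    name = stage("radiance")
    try:
        radiance = dn_to_radiance(ntl_dn, exponent=config.radiance_exponent)
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    name = stage("normalize")
    try:
        lj_nor = minmax_normalize(radiance, mask=mask)
        lj_nor = lj_nor.with_values(np.clip(lj_nor.values, 0.0, 1.0))
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    name = stage("evi_composite")
    try:
        evi_max = max_composite(evi_layers)
        if config.evi_clamp:
            evi_max = evi_max.with_values(np.clip(evi_max.values, 0.0, 1.0))
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    name = stage("hsi")
    try:
        hsi = compute_hsi(evi_max, lj_nor, eps=config.hsi_eps)
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    sweep = None
    rnd = weights = power_fit = None
    if config.index == "rnahsi":
        name = stage("bandwidth_sweep")
        try:
            if config.bandwidths is not None:
                sweep = bandwidth_sweep(
                    roads, zones, config.bandwidths, target,
                    default_bandwidth=config.chosen_bandwidth,
                    choose=config.bandwidth_choice,
                )
                bandwidth = sweep.chosen
            else:
                bandwidth = config.chosen_bandwidth
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

        name = stage("class_kde")
        try:
            classes = roads.classes_present()
            per_class = {
                cls: line_kde(
                    roads, cls, bandwidth, target,
                    spacing=config.kde_spacing, method=config.kde_method,
                )
                for cls in classes
            }
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

        name = stage("pca_weights")
        try:
            import pandas as pd

            sums = pd.DataFrame(
                {
                    cls: zonal_sum(g, zones, labels=labels).to_numpy()
                    for cls, g in per_class.items()
                },
                index=zones.zone_ids,
            )
            weights = pca_class_weights(sums)
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

        name = stage("composite_rnd")
        try:
            rnd = composite_rnd(per_class, weights)
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

        name = stage("power_fit")
        try:
            counts = np.bincount(labels[labels >= 0].ravel(), minlength=len(zones))
            mean_rnd = np.divide(
                zonal_sum(rnd, zones, labels=labels).to_numpy(),
                counts, out=np.zeros(len(zones)), where=counts > 0,
            )
            mean_density = zones.populations / zones.areas_km2
            power_fit = fit_power_law(mean_rnd, mean_density)
            log.info(
                "power fit: a=%.4g b=%.4f R2=%.3f (%d zones, %d dropped)",
                power_fit.coefficient, power_fit.exponent,
                power_fit.r_squared, power_fit.n_zones, power_fit.n_dropped,
            )
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

        name = stage("rnahsi")
        try:
            rnahsi = compute_rnahsi(hsi, rnd, power_fit.exponent)
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
    else:
        rnahsi = hsi  # settlement index without the road adjustment

    name = stage("calibration")
    try:
        sums = zonal_sum(rnahsi, zones, labels=labels).to_numpy()
        linear_fit = fit_linear_calibration(sums, zones.populations)
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    name = stage("disaggregation")
    try:
        population = disaggregate(
            rnahsi, zones, fit=linear_fit, mode=config.mode, labels=labels
        )
        # uncorrected regression total -> the overall-bias correction factor
        raw_est = float(
            np.maximum(
                linear_fit.slope * np.nan_to_num(rnahsi.values)
                + linear_fit.intercept / max(int((labels >= 0).sum()), 1),
                0.0,
            )[labels >= 0].sum()
        )
        correction = (
            zones.total_population() / raw_est if raw_est > 0 else float("nan")
        )
        log.info("correction factor: %.4f", correction)
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    name = stage("density")
    try:
        density = to_density(population)
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    name = stage("assessment")
    try:
        report = residual_report(population, zones, labels=labels)
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    log.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return PipelineResult(
        hsi=hsi,
        rnahsi=rnahsi,
        population=population,
        density=density,
        report=report,
        rnd=rnd,
        weights=weights,
        power_fit=power_fit,
        sweep=sweep,
        linear_fit=linear_fit,
        correction=correction,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load inputs from the config paths, run, and write all outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("rnahsi")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    try:
        ntl = read_geotiff(config.inputs.ntl)
        evi = [read_geotiff(p) for p in config.inputs.evi]
        roads = read_roads_geojson(config.inputs.roads, crs=ntl.crs)
        census = (
            read_census_csv(config.inputs.census) if config.inputs.census else None
        )
        zones = read_zones_geojson(config.inputs.zones, census=census, crs=ntl.crs)
        result = run_from_data(ntl, evi, roads, zones, config)

        files: dict[str, Path] = {}

        def save_grid(key: str, grid: Grid) -> None:
            p = out / f"{key}.tif"
            write_geotiff(grid, p)
            files[key] = p

        save_grid("hsi", result.hsi)
        if result.rnd is not None:
            save_grid("rnd", result.rnd)
        save_grid("rnahsi", result.rnahsi)
        save_grid("population", result.population)
        save_grid("density", result.density)
        if result.sweep is not None:
            result.sweep.to_csv(out / "sweep.csv")
            files["sweep"] = out / "sweep.csv"
        if result.weights is not None:
            (out / "weights.json").write_text(
                json.dumps(
                    {
                        "weights": result.weights.weights,
                        "variance_explained": result.weights.variance_explained,
                    },
                    indent=2, sort_keys=True,
                )
            )
            files["weights"] = out / "weights.json"
        if result.power_fit is not None:
            pf = result.power_fit
            (out / "powerfit.json").write_text(
                json.dumps(
                    {
                        "coefficient": pf.coefficient,
                        "exponent": pf.exponent,
                        "r_squared": pf.r_squared,
                        "n_zones": pf.n_zones,
                        "n_dropped": pf.n_dropped,
                    },
                    indent=2, sort_keys=True,
                )
            )
            files["powerfit"] = out / "powerfit.json"
        result.report.to_json(out / "accuracy.json")
        files["accuracy"] = out / "accuracy.json"
        result.report.to_csv(out / "accuracy_zones.csv")
        files["accuracy_zones"] = out / "accuracy_zones.csv"

        manifest = {
            "tool": "rnahsi",
            "version": __version__,
            "config_hash": config.config_hash(),
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in files.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        files["manifest"] = out / "manifest.json"
        files["log"] = out / "run.log"
        result.files = files
        return result
    finally:
        root.removeHandler(fh)
        fh.close()
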