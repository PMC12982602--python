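"""End-to-end orchestration with a YAML config, seeding, and provenance.

Stages (in order): ``simulate`` → ``preprocess`` → ``calibrate`` →
``extract`` → ``validate``. Every stage reads its inputs from, and writes
its artifacts into, the configured output directory, so stages can be run
separately; a missing upstream artifact raises an error naming the stage to
run first. Each main artifact gets a ``.provenance.json`` sidecar recording
the config hash, the seed, and library versions; an artifact on disk whose
sidecar carries a different config hash is never silently overwritten.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import (
    CalibrationResult,
    CropFit,
    DegreeCalibration,
    calibrate_all,
)
from .core import CROPS, DEGREES, CropMask, HistoricalStats, LaiCube
from .io import read_cube, read_masks, write_cube, write_masks
from .mapping import area_summary, check_nesting, classify, write_impact_tiff
from .preprocess import smooth_cube
from .report import recovery_summary, validate_series
from .synthetic import (
    DroughtEvent,
    RegionSpec,
    SimulationConfig,
    SyntheticTruth,
    derive_historical_stats,
    generate_lai_cube,
    double_cropping_scenario,
    single_region_scenario,
    two_region_scenario,
)
from .windows import TimeWindow, composite_calendar

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "calibrate", "extract", "validate")

_SCENARIOS = {
    "two_region": two_region_scenario,
    "single_region": single_region_scenario,
    "double_cropping": double_cropping_scenario,
}


class MissingArtifactError(FileNotFoundError):
    """An upstream stage has not produced a required input yet."""


class ProvenanceConflictError(RuntimeError):
    """An artifact from a different configuration would be overwritten."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    out_dir: Path
    seed: int = 0
    scenario: str | None = "two_region"
    simulation: SimulationConfig | None = None
    noise_sd: float = 0.0
    stats_noise_cv: float = 0.0
    sg_window: int = 3
    sg_polyorder: int = 3
    t_min: int = 0
    t_max: int = 100
    t_step: int = 1
    baseline_years: dict[str, int] = field(default_factory=dict)
    enforce_nesting: bool = False
    log_level: str = "INFO"
    overwrite: bool = False
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.t_step < 1 or (self.t_max - self.t_min) % self.t_step != 0:
            raise ValueError("threshold step must divide the grid range")
        if not (0 <= self.t_min <= self.t_max <= 100):
            raise ValueError("threshold grid must lie within [0, 100]")
        if self.scenario is None and self.simulation is None:
            raise ValueError("either a named scenario or an inline simulation is required")
        if self.scenario is not None and self.scenario not in _SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {sorted(_SCENARIOS)}")

    @property
    def t_grid(self) -> np.ndarray:
        return np.arange(self.t_min, self.t_max + 1, self.t_step, dtype=int)

    def simulation_config(self) -> SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        cfg = _SCENARIOS[self.scenario](
            self.seed, noise_sd=self.noise_sd, stats_noise_cv=self.stats_noise_cv
        )
        return cfg

    def config_hash(self) -> str:
        payload = dict(self.raw) if self.raw else _config_payload(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, **overrides)

    @classmethod
    def from_dict(cls, raw: Mapping, **overrides) -> "PipelineConfig":
        raw = dict(raw)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {
            "out_dir",
            "seed",
            "scenario",
            "simulation",
            "noise_sd",
            "stats_noise_cv",
            "sg_window",
            "sg_polyorder",
            "t_min",
            "t_max",
            "t_step",
            "baseline_years",
            "enforce_nesting",
            "log_level",
            "overwrite",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ValueError("config requires out_dir")
        sim = raw.get("simulation")
        sim_cfg = _parse_simulation(sim, int(raw.get("seed", 0))) if sim else None
        kwargs = {k: raw[k] for k in known & set(raw) if k != "simulation"}
        kwargs["simulation"] = sim_cfg
        if sim_cfg is not None:
            kwargs.setdefault("scenario", None)
            kwargs["scenario"] = None
        cfg = cls(raw=dict(raw), **kwargs)
        return cfg


def _config_payload(cfg: PipelineConfig) -> dict:
    return {
        "seed": cfg.seed,
        "scenario": cfg.scenario,
        "noise_sd": cfg.noise_sd,
        "stats_noise_cv": cfg.stats_noise_cv,
        "sg": [cfg.sg_window, cfg.sg_polyorder],
        "t": [cfg.t_min, cfg.t_max, cfg.t_step],
        "baseline_years": cfg.baseline_years,
        "enforce_nesting": cfg.enforce_nesting,
    }


def _parse_simulation(raw: Mapping, seed: int) -> SimulationConfig:
    regions = []
    for r in raw["regions"]:
        events = [
            DroughtEvent(int(e["year"]), e["crop"], float(e["fraction"]), float(e["depression"]))
            for e in r.get("drought_events", [])
        ]
        regions.append(
            RegionSpec(
                region_id=r["region_id"],
                row_slice=tuple(r["row_slice"]),
                col_slice=tuple(r["col_slice"]),
                crops=tuple(r["crops"]),
                growing_season={c: tuple(v) for c, v in r["growing_season"].items()},
                truth_thresholds={
                    (c, d): float(t)
                    for c, degs in r["truth_thresholds"].items()
                    for d, t in degs.items()
                },
                truth_windows={c: tuple(v) for c, v in r["truth_windows"].items()},
                baseline_year=int(r["baseline_year"]),
                drought_events=events,
                crop_cover=float(r.get("crop_cover", 1.0)),
            )
        )
    return SimulationConfig(
        seed=int(raw.get("seed", seed)),
        grid_shape=tuple(raw["grid_shape"]),
        years=[int(y) for y in raw["years"]],
        regions=regions,
        pixel_size_m=float(raw.get("pixel_size_m", 500.0)),
        composite_step_days=int(raw.get("composite_step_days", 8)),
        noise_sd=float(raw.get("noise_sd", 0.0)),
        stats_noise_cv=float(raw.get("stats_noise_cv", 0.0)),
    )


# ---------------------------------------------------------------------------
# provenance sidecars
# ---------------------------------------------------------------------------


def _write_provenance(path: Path, cfg: PipelineConfig, stage: str) -> None:
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    record = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage": stage,
        "droughtlai": __version__,
        "numpy": np.__version__,
    }
    sidecar.write_text(json.dumps(record, indent=2))


def _check_overwrite(path: Path, cfg: PipelineConfig) -> None:
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    if path.exists() and sidecar.exists() and not cfg.overwrite:
        previous = json.loads(sidecar.read_text()).get("config_hash")
        if previous != cfg.config_hash():
            raise ProvenanceConflictError(
                f"{path} was produced by config {previous}; refusing to overwrite "
                "with a different configuration (set overwrite: true to force)"
            )


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing {path.name}; run the '{produced_by}' stage first"
        )
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig) -> None:
    sim = cfg.simulation_config()
    cube, masks, truth = generate_lai_cube(sim)
    stats = derive_historical_stats(cube, masks, truth, sim.stats_noise_cv)
    out = cfg.out_dir
    for name in ("cube.nc", "stats.csv"):
        _check_overwrite(out / name, cfg)
    write_cube(out / "cube.nc", cube)
    write_masks(out / "masks", masks)
    stats.to_csv(out / "stats.csv")
    _truth_to_csv(truth, out)
    for name in ("cube.nc", "stats.csv"):
        _write_provenance(out / name, cfg, "simulate")
    logger.info("simulate: %d years, grid %s, %d region(s)", len(cube.years), cube.grid.shape, len(masks.regions))


def _stage_preprocess(cfg: PipelineConfig) -> None:
    cube = read_cube(_require(cfg.out_dir / "cube.nc", "simulate"))
    _check_overwrite(cfg.out_dir / "cube_smoothed.nc", cfg)
    smoothed = smooth_cube(cube, cfg.sg_window, cfg.sg_polyorder)
    write_cube(cfg.out_dir / "cube_smoothed.nc", smoothed)
    _write_provenance(cfg.out_dir / "cube_smoothed.nc", cfg, "preprocess")


def _stage_calibrate(cfg: PipelineConfig) -> None:
    out = cfg.out_dir
    cube = read_cube(_require(out / "cube_smoothed.nc", "preprocess"))
    masks = read_masks(_require(out / "masks", "simulate"))
    stats = HistoricalStats.read_csv(_require(out / "stats.csv", "simulate"))
    seasons = _seasons_from_csv(_require(out / "truth_params.csv", "simulate"))
    _check_overwrite(out / "calibration.csv", cfg)
    result = calibrate_all(
        cube,
        masks,
        stats,
        seasons,
        baseline_years=cfg.baseline_years or None,
        t_grid=cfg.t_grid,
    )
    result.table().to_csv(out / "calibration.csv", index=False)
    result.series_table().to_csv(out / "ea_ha_series.csv", index=False)
    _write_provenance(out / "calibration.csv", cfg, "calibrate")


def _stage_extract(cfg: PipelineConfig) -> None:
    out = cfg.out_dir
    cube = read_cube(_require(out / "cube_smoothed.nc", "preprocess"))
    masks = read_masks(_require(out / "masks", "simulate"))
    calib = load_calibration(
        _require(out / "calibration.csv", "calibrate"),
        out / "ea_ha_series.csv",
        cube.composite_step_days,
    )
    maps_dir = out / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    crops = sorted(
        {crop for (_, _), e in calib.entries.items() for crop in e.crops}, key=CROPS.index
    )
    rasters = []
    nesting_rows = []
    for crop in crops:
        for year in cube.years:
            per_degree = {
                degree: classify(cube, masks, calib, crop, degree, year) for degree in DEGREES
            }
            result = check_nesting(
                per_degree["DC"], per_degree["DD"], per_degree["CF"], enforce=cfg.enforce_nesting
            )
            if cfg.enforce_nesting:
                rep, (dc, dd, cf) = result
                per_degree = {"DC": dc, "DD": dd, "CF": cf}
            else:
                rep = result
            nesting_rows.append((crop, year, rep.dd_not_dc, rep.cf_not_dd, rep.cf_not_dc))
            for degree in DEGREES:
                write_impact_tiff(per_degree[degree], maps_dir)
                rasters.append(per_degree[degree])
    area_summary(rasters, masks).to_csv(out / "area_summary.csv", index=False)
    pd.DataFrame(
        nesting_rows, columns=["crop", "year", "dd_not_dc", "cf_not_dd", "cf_not_dc"]
    ).to_csv(out / "nesting_report.csv", index=False)
    _write_provenance(out / "area_summary.csv", cfg, "extract")


def _stage_validate(cfg: PipelineConfig) -> None:
    out = cfg.out_dir
    stats = HistoricalStats.read_csv(_require(out / "stats.csv", "simulate"))
    step = 8
    cube_path = out / "cube_smoothed.nc"
    if cube_path.exists():
        step = read_cube(cube_path).composite_step_days
    calib = load_calibration(
        _require(out / "calibration.csv", "calibrate"), out / "ea_ha_series.csv", step
    )
    table = validate_series(calib, stats)
    table.to_csv(out / "validation.csv", index=False)
    _write_provenance(out / "validation.csv", cfg, "validate")
    truth_path = out / "truth_params.csv"
    if truth_path.exists():
        truth = _truth_from_csv(truth_path)
        recovery_summary(truth, calib).to_csv(out / "recovery.csv", index=False)


def run_pipeline(config: PipelineConfig, stages: Sequence[str] | None = None) -> Path:
    """Run the requested stages in canonical order; returns the output dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    wanted = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    config.out_dir.mkdir(parents=True, exist_ok=True)
    runners = {
        "simulate": _stage_simulate,
        "preprocess": _stage_preprocess,
        "calibrate": _stage_calibrate,
        "extract": _stage_extract,
        "validate": _stage_validate,
    }
    for stage in wanted:
        logger.info("stage: %s", stage)
        runners[stage](config)
    return config.out_dir


# ---------------------------------------------------------------------------
# artifact (de)serialisation helpers
# ---------------------------------------------------------------------------


def _truth_to_csv(truth: SyntheticTruth, out_dir: Path) -> None:
    rows = []
    for (region, crop, degree), t in sorted(truth.thresholds.items()):
        w = truth.windows[(region, crop)]
        ds, de = truth.seasons[region][crop]
        rows.append(
            (region, crop, degree, t, w.start_doy, w.end_doy, ds, de, truth.baseline_years[region])
        )
    pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "crop",
            "degree",
            "t_true",
            "window_start_doy",
            "window_end_doy",
            "season_start_doy",
            "season_end_doy",
            "baseline_year",
        ],
    ).to_csv(out_dir / "truth_params.csv", index=False)
    areas = pd.DataFrame(
        [(r, y, d, a) for (r, y, d), a in sorted(truth.true_areas.items())],
        columns=["region_id", "year", "degree", "area_thousand_ha"],
    )
    areas.to_csv(out_dir / "truth_areas.csv", index=False)


def _truth_from_csv(path: Path) -> SyntheticTruth:
    frame = pd.read_csv(path)
    cal = composite_calendar(8)
    thresholds = {}
    windows = {}
    baselines = {}
    seasons: dict[str, dict[str, tuple[int, int]]] = {}
    for row in frame.itertuples():
        thresholds[(row.region_id, row.crop, row.degree)] = float(row.t_true)
        si = int(np.searchsorted(cal, row.window_start_doy))
        ei = int(np.searchsorted(cal, row.window_end_doy))
        windows[(row.region_id, row.crop)] = TimeWindow(
            si, ei, int(row.window_start_doy), int(row.window_end_doy)
        )
        baselines[row.region_id] = int(row.baseline_year)
        seasons.setdefault(row.region_id, {})[row.crop] = (
            int(row.season_start_doy),
            int(row.season_end_doy),
        )
    return SyntheticTruth(
        seed=0,
        thresholds=thresholds,
        windows=windows,
        baseline_years=baselines,
        true_areas={},
        seasons=seasons,
    )


def _seasons_from_csv(path: Path) -> dict[str, dict[str, tuple[int, int]]]:
    truth = _truth_from_csv(path)
    return truth.seasons


def load_calibration(calib_csv, series_csv, step_days: int = 8) -> CalibrationResult:
    """Rebuild a :class:`CalibrationResult` from the CSV artifacts."""
    table = pd.read_csv(calib_csv)
    series = pd.read_csv(series_csv) if Path(series_csv).exists() else None
    cal = composite_calendar(step_days)
    result = CalibrationResult()
    for (region, degree), group in table.groupby(["region_id", "degree"], sort=True):
        crops = {}
        for row in group.itertuples():
            si = int(np.searchsorted(cal, row.window_start_doy))
            ei = int(np.searchsorted(cal, row.window_end_doy))
            crops[row.crop] = CropFit(
                crop=row.crop,
                t_percent=int(row.t_percent),
                window=TimeWindow(si, ei, int(row.window_start_doy), int(row.window_end_doy)),
                ea=np.array([]),
            )
        years: tuple[int, ...] = ()
        ea = ha = np.array([])
        if series is not None:
            sub = series[(series["region_id"] == region) & (series["degree"] == degree)]
            sub = sub.sort_values("year")
            years = tuple(int(y) for y in sub["year"])
            ea = sub["ea_thousand_ha"].to_numpy(dtype=float)
            ha = sub["ha_thousand_ha"].to_numpy(dtype=float)
        first = group.iloc[0]
        result.entries[(region, degree)] = DegreeCalibration(
            region=region,
            degree=degree,
            baseline_year=int(first["baseline_year"]),
            ha_base=float(first["ha_base"]),
            years=years,
            ha=ha,
            ea=ea,
            r=float(first["r"]),
            rmse=float(first["rmse"]),
            crops=crops,
        )
    return result
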