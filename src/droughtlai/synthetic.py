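"""Seeded synthetic study scenarios: LAI cubes, crop masks, and statistics.

The generator emulates the study design that the calibration method expects
from real data:

* 8-day LAI composites (46 per year) on a 500 m grid over multiple years,
  with a smooth unimodal phenology per crop season and per-pixel amplitude
  heterogeneity (the spatial variability the *relative* threshold is built
  to absorb);
* static crop-coverage masks per crop class and a rectangular region
  partition;
* region-level drought events: in an event year, a chosen fraction of the
  region's crop pixels has its LAI over the crop's truth window multiplied
  by (1 - depression);
* annual historical statistics derived from the cube under known ground
  truth thresholds and windows, optionally perturbed by multiplicative
  lognormal noise — the parameter-recovery surface for every downstream
  stage.

The baseline year carries no drought events, so extraction against it
returns zero there and the statistics' baseline value is the region-wide
minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import CROPS, DEGREES, CropMask, GridSpec, HistoricalStats, LaiCube
from .calibrate import extracted_area
from .windows import TimeWindow, composite_calendar, season_composite_indices, window_mean


@dataclass(frozen=True)
class DroughtEvent:
    """One region-level drought: (year, crop, pixel fraction, LAI depression)."""

    year: int
    crop: str
    fraction: float
    depression: float

    def __post_init__(self) -> None:
        if self.crop not in CROPS:
            raise ValueError(f"unknown crop {self.crop!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("event fraction must be in [0, 1]")
        if not 0.0 <= self.depression < 1.0:
            raise ValueError("depression factor must be in [0, 1)")


@dataclass
class RegionSpec:
    """One rectangular region: crops, seasons, ground truth, drought events."""

    region_id: str
    row_slice: tuple[int, int]
    col_slice: tuple[int, int]
    crops: tuple[str, ...]
    growing_season: dict[str, tuple[int, int]]  # crop -> (doy_start, doy_end)
    truth_thresholds: dict[tuple[str, str], float]  # (crop, degree) -> percent
    truth_windows: dict[str, tuple[int, int]]  # crop -> (doy_start, doy_end)
    baseline_year: int
    drought_events: list[DroughtEvent] = field(default_factory=list)
    crop_cover: float = 1.0  # fraction of block pixels carrying each crop

    def validate(self, years: Sequence[int]) -> None:
        for crop in self.crops:
            if crop not in CROPS:
                raise ValueError(f"unknown crop {crop!r} in region {self.region_id}")
            ds, de = self.growing_season[crop]
            if not (1 <= ds < de <= 365):
                raise ValueError(f"bad growing season for {crop!r} in {self.region_id}")
            ws, we = self.truth_windows[crop]
            if not (ds <= ws <= we <= de):
                raise ValueError(f"truth window outside season for {crop!r} in {self.region_id}")
            t = [self.truth_thresholds[(crop, d)] for d in DEGREES]
            if not all(0 <= x <= 100 for x in t):
                raise ValueError("truth thresholds must be percentages in [0, 100]")
            if not (t[0] >= t[1] >= t[2]):
                raise ValueError(
                    f"truth thresholds must decrease with severity (DC >= DD >= CF) "
                    f"for {crop!r} in {self.region_id}"
                )
        if self.baseline_year not in years:
            raise ValueError(f"baseline year {self.baseline_year} not a simulated year")
        if not 0.0 < self.crop_cover <= 1.0:
            raise ValueError("crop_cover must be in (0, 1]")
        for ev in self.drought_events:
            if ev.year not in years:
                raise ValueError(f"event year {ev.year} not simulated ({self.region_id})")
            if ev.crop not in self.crops:
                raise ValueError(f"event crop {ev.crop!r} not grown in {self.region_id}")
            if ev.year == self.baseline_year:
                raise ValueError(f"drought event in baseline year of {self.region_id}")


@dataclass
class SimulationConfig:
    """Full scenario description; the RNG seed fixes every random draw."""

    seed: int
    grid_shape: tuple[int, int]
    years: Sequence[int]
    regions: list[RegionSpec]
    pixel_size_m: float = 500.0
    composite_step_days: int = 8
    noise_sd: float = 0.0  # additive LAI noise per composite
    stats_noise_cv: float = 0.0  # CV of the lognormal factor on statistics
    amplitude_range: tuple[float, float] = (2.0, 6.0)  # peak LAI per crop pixel
    background_lai: float = 0.1
    epsg: int = 32649

    def validate(self) -> None:
        if self.grid_shape[0] <= 0 or self.grid_shape[1] <= 0:
            raise ValueError("grid_shape must be positive")
        years = [int(y) for y in self.years]
        if len(years) < 1 or any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        n_comp = len(composite_calendar(self.composite_step_days))
        if n_comp < 2:
            raise ValueError("composite step must give at least 2 composites per year")
        if self.noise_sd < 0 or self.stats_noise_cv < 0:
            raise ValueError("noise terms must be non-negative")
        if not self.regions:
            raise ValueError("at least one region required")
        for r in self.regions:
            r.validate(years)


@dataclass
class SyntheticTruth:
    """Ground truth of a scenario: parameters and noise-free areas.

    ``true_areas`` maps (region, year, degree) to the impacted area in
    thousand ha extracted from the generated cube under the truth thresholds
    and windows — exactly what noise-free statistics report.
    """

    seed: int
    thresholds: dict[tuple[str, str, str], float]  # (region, crop, degree) -> percent
    windows: dict[tuple[str, str], TimeWindow]  # (region, crop)
    baseline_years: dict[str, int]
    true_areas: dict[tuple[str, int, str], float]
    seasons: dict[str, dict[str, tuple[int, int]]]


def _bell(doys: np.ndarray, doy_start: int, doy_end: int) -> np.ndarray:
    """Raised-cosine phenology shape: 0 at season edges, 1 at mid-season."""
    x = (doys - doy_start) / (doy_end - doy_start)
    inside = (x >= 0) & (x <= 1)
    return np.where(inside, 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(x, 0, 1))), 0.0)


def _snap_window(doy_start: int, doy_end: int, step: int) -> TimeWindow:
    cal = composite_calendar(step)
    idx = season_composite_indices(doy_start, doy_end, step)
    return TimeWindow(int(idx[0]), int(idx[-1]), int(cal[idx[0]]), int(cal[idx[-1]]))


def generate_lai_cube(config: SimulationConfig) -> tuple[LaiCube, CropMask, SyntheticTruth]:
    """Simulate the LAI cube, crop/region masks, and ground truth.

    Deterministic given ``config.seed``: identical configs produce
    bit-identical cubes. Per-pixel crop amplitudes are drawn once and reused
    for every year, so with zero noise and no events each year repeats the
    baseline phenology exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_rows, n_cols = config.grid_shape
    years = tuple(int(y) for y in config.years)
    doys = composite_calendar(config.composite_step_days)
    n_comp = len(doys)
    grid = GridSpec(
        n_rows=n_rows, n_cols=n_cols, pixel_size=config.pixel_size_m, epsg=config.epsg
    )

    region_ids = np.zeros((n_rows, n_cols), dtype=np.int16)
    region_names: dict[int, str] = {}
    masks: dict[str, np.ndarray] = {}
    signal = np.full((n_comp, n_rows, n_cols), config.background_lai, dtype=float)

    for label, region in enumerate(config.regions, start=1):
        r0, r1 = region.row_slice
        c0, c1 = region.col_slice
        if not (0 <= r0 < r1 <= n_rows and 0 <= c0 < c1 <= n_cols):
            raise ValueError(f"region block of {region.region_id} outside grid")
        block = np.zeros((n_rows, n_cols), dtype=bool)
        block[r0:r1, c0:c1] = True
        if (region_ids[block] != 0).any():
            raise ValueError(f"region {region.region_id} overlaps another region")
        region_ids[block] = label
        region_names[label] = region.region_id

        for crop in region.crops:
            cover = block.copy()
            if region.crop_cover < 1.0:
                keep = rng.random(cover.sum()) < region.crop_cover
                cover[block] = keep
            masks.setdefault(crop, np.zeros((n_rows, n_cols), dtype=bool))
            masks[crop] |= cover
            # fixed per-pixel amplitude: spatial heterogeneity, stable in time
            amp = rng.uniform(*config.amplitude_range, size=int(cover.sum()))
            ds, de = region.growing_season[crop]
            shape = _bell(doys.astype(float), ds, de)  # (n_comp,)
            rr, cc = np.where(cover)
            signal[:, rr, cc] += shape[:, None] * amp[None, :]

    # replicate the annual cycle, then apply drought events per year
    values = np.repeat(signal[None, :, :, :], len(years), axis=0)
    truth_windows: dict[tuple[str, str], TimeWindow] = {}
    thresholds: dict[tuple[str, str, str], float] = {}
    baseline_years: dict[str, int] = {}
    seasons: dict[str, dict[str, tuple[int, int]]] = {}

    for region in config.regions:
        baseline_years[region.region_id] = int(region.baseline_year)
        seasons[region.region_id] = {c: tuple(region.growing_season[c]) for c in region.crops}
        block = region_ids == [k for k, v in region_names.items() if v == region.region_id][0]
        for crop in region.crops:
            w = _snap_window(*region.truth_windows[crop], config.composite_step_days)
            truth_windows[(region.region_id, crop)] = w
            for degree in DEGREES:
                thresholds[(region.region_id, crop, degree)] = float(
                    region.truth_thresholds[(crop, degree)]
                )
        for ev in region.drought_events:
            w = truth_windows[(region.region_id, ev.crop)]
            crop_pixels = np.where(masks[ev.crop] & block)
            n_pix = crop_pixels[0].size
            n_hit = int(round(ev.fraction * n_pix))
            pick = rng.choice(n_pix, size=n_hit, replace=False)
            rr = crop_pixels[0][pick]
            cc = crop_pixels[1][pick]
            yi = years.index(ev.year)
            sl = slice(w.start_index, w.end_index + 1)
            values[yi, sl, rr, cc] *= 1.0 - ev.depression

    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
        np.clip(values, 0.0, None, out=values)

    cube = LaiCube(
        values=values,
        valid=np.ones_like(values, dtype=bool),
        years=years,
        composite_doys=doys,
        grid=grid,
    )
    crop_mask = CropMask(masks=masks, region_ids=region_ids, region_names=region_names, grid=grid)
    truth = SyntheticTruth(
        seed=int(config.seed),
        thresholds=thresholds,
        windows=truth_windows,
        baseline_years=baseline_years,
        true_areas={},
        seasons=seasons,
    )
    truth.true_areas = _true_areas(cube, crop_mask, truth)
    return cube, crop_mask, truth


def _true_areas(
    cube: LaiCube, masks: CropMask, truth: SyntheticTruth
) -> dict[tuple[str, int, str], float]:
    """Noise-free statistics: extraction under the truth parameters.

    Uses the public window-mean and extraction operations — the same
    indicator rule the calibration searches over.
    """
    out: dict[tuple[str, int, str], float] = {}
    for region in sorted(truth.baseline_years):
        base_year = truth.baseline_years[region]
        crops = sorted(truth.seasons[region], key=CROPS.index)
        base_means = {}
        for crop in crops:
            w = truth.windows[(region, crop)]
            base_means[crop] = window_mean(cube, w, base_year, masks.crop_in_region(crop, region))
        for year in cube.years:
            actual = {
                crop: window_mean(
                    cube, truth.windows[(region, crop)], year, masks.crop_in_region(crop, region)
                )
                for crop in crops
            }
            for degree in DEGREES:
                area = 0.0
                for crop in crops:
                    t = truth.thresholds[(region, crop, degree)]
                    area += extracted_area(actual[crop], base_means[crop], t)
                out[(region, year, degree)] = area
    return out


def derive_historical_stats(
    cube: LaiCube,
    masks: CropMask,
    truth: SyntheticTruth,
    stats_noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> HistoricalStats:
    """Annual statistics implied by the truth, with multiplicative noise.

    Each (region, year, degree) entry is the truth extraction times a
    lognormal factor with unit mean and coefficient of variation
    ``stats_noise_cv`` (factor identically 1 when the CV is 0). The baseline
    year's entry is the extraction against itself — zero — so it retains the
    region-wide minimum across degrees.
    """
    if stats_noise_cv < 0:
        raise ValueError("stats_noise_cv must be non-negative")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 910]))
    areas = _true_areas(cube, masks, truth)
    sigma = float(np.sqrt(np.log1p(stats_noise_cv**2)))
    records = []
    for (region, year, degree), area in sorted(areas.items()):
        if stats_noise_cv > 0:
            factor = float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
        else:
            factor = 1.0
        records.append((region, int(year), degree, area * factor))
    return HistoricalStats.from_records(records)


def fill_missing_year_masks(
    masks_by_year: Mapping[int, np.ndarray], years: Sequence[int]
) -> dict[int, np.ndarray]:
    """Extend per-year coverage masks by copying the last available year.

    Mirrors the handling of a crop-coverage product that ends before the
    study period does (the missing year inherits the previous year's mask).
    """
    out: dict[int, np.ndarray] = {}
    last = None
    for year in sorted(int(y) for y in years):
        if year in masks_by_year:
            last = np.asarray(masks_by_year[year], dtype=bool)
        elif last is None:
            raise ValueError(f"no mask available at or before year {year}")
        out[year] = last.copy()
    return out


# ---------------------------------------------------------------------------
# canonical study scenarios
# ---------------------------------------------------------------------------


def two_region_scenario(
    seed: int = 0, *, noise_sd: float = 0.0, stats_noise_cv: float = 0.0
) -> SimulationConfig:
    """Two single-crop regions, 15 years, pinned drought severities.

    The northern region grows a summer-harvest crop, the southern an
    autumn-harvest crop (its season spans DOY 145-273, the 17-composite
    span that yields 153 candidate windows). Each region sees three or four
    drought events whose depressions place the affected LAI ratio exactly at
    a truth-threshold boundary, making every severity degree identifiable
    from the annual statistics.
    """
    years = list(range(2006, 2021))
    north = RegionSpec(
        region_id="north",
        row_slice=(0, 20),
        col_slice=(0, 30),
        crops=("summer",),
        growing_season={"summer": (65, 177)},
        truth_thresholds={("summer", "DC"): 80, ("summer", "DD"): 60, ("summer", "CF"): 40},
        truth_windows={"summer": (105, 145)},
        baseline_year=2006,
        drought_events=[
            DroughtEvent(2009, "summer", 0.20, 0.20),
            DroughtEvent(2012, "summer", 0.35, 0.40),
            DroughtEvent(2017, "summer", 0.50, 0.60),
        ],
    )
    south = RegionSpec(
        region_id="south",
        row_slice=(20, 40),
        col_slice=(0, 30),
        crops=("autumn",),
        growing_season={"autumn": (145, 273)},
        truth_thresholds={("autumn", "DC"): 85, ("autumn", "DD"): 65, ("autumn", "CF"): 45},
        truth_windows={"autumn": (185, 225)},
        baseline_year=2006,
        drought_events=[
            DroughtEvent(2007, "autumn", 0.25, 0.15),
            DroughtEvent(2011, "autumn", 0.40, 0.35),
            DroughtEvent(2014, "autumn", 0.30, 0.55),
            DroughtEvent(2019, "autumn", 0.55, 0.55),
        ],
    )
    return SimulationConfig(
        seed=seed,
        grid_shape=(40, 30),
        years=years,
        regions=[north, south],
        noise_sd=noise_sd,
        stats_noise_cv=stats_noise_cv,
    )


def single_region_scenario(
    seed: int = 0, *, noise_sd: float = 0.0, stats_noise_cv: float = 0.05
) -> SimulationConfig:
    """Reduced scenario for replicated recovery experiments.

    One autumn-crop region on a 12x12 grid, 15 years, three pinned drought
    events, and (by default) 5% lognormal noise on the statistics. The LAI
    signal is canopy-only (no additive background): a non-canopy background
    does not scale with the per-pixel amplitude, so partially overlapping
    windows would turn the relative-LAI ratio into a per-pixel continuum
    and the threshold would be identifiable from a handful of noisy annual
    statistics only up to that smearing. With a canopy-only signal the
    candidate family is discrete and the truth threshold is recoverable.
    """
    years = list(range(2006, 2021))
    region = RegionSpec(
        region_id="plain",
        row_slice=(0, 12),
        col_slice=(0, 12),
        crops=("autumn",),
        growing_season={"autumn": (145, 273)},
        truth_thresholds={("autumn", "DC"): 80, ("autumn", "DD"): 60, ("autumn", "CF"): 40},
        truth_windows={"autumn": (185, 225)},
        baseline_year=2006,
        drought_events=[
            DroughtEvent(2009, "autumn", 0.25, 0.20),
            DroughtEvent(2013, "autumn", 0.45, 0.40),
            DroughtEvent(2018, "autumn", 0.60, 0.60),
        ],
    )
    return SimulationConfig(
        seed=seed,
        grid_shape=(12, 12),
        years=years,
        regions=[region],
        noise_sd=noise_sd,
        stats_noise_cv=stats_noise_cv,
        background_lai=0.0,
    )


def double_cropping_scenario(seed: int = 0, *, noise_sd: float = 0.0) -> SimulationConfig:
    """One region with summer and autumn crops sharing pixels (double cropping)."""
    years = list(range(2006, 2021))
    region = RegionSpec(
        region_id="valley",
        row_slice=(0, 16),
        col_slice=(0, 16),
        crops=("summer", "autumn"),
        growing_season={"summer": (65, 177), "autumn": (185, 297)},
        truth_thresholds={
            ("summer", "DC"): 80,
            ("summer", "DD"): 60,
            ("summer", "CF"): 40,
            ("autumn", "DC"): 80,
            ("autumn", "DD"): 60,
            ("autumn", "CF"): 40,
        },
        truth_windows={"summer": (105, 145), "autumn": (225, 265)},
        baseline_year=2006,
        drought_events=[
            DroughtEvent(2008, "summer", 0.30, 0.20),
            DroughtEvent(2011, "summer", 0.45, 0.40),
            DroughtEvent(2016, "summer", 0.60, 0.60),
            DroughtEvent(2009, "autumn", 0.25, 0.20),
            DroughtEvent(2013, "autumn", 0.50, 0.40),
            DroughtEvent(2019, "autumn", 0.40, 0.60),
        ],
    )
    return SimulationConfig(
        seed=seed,
        grid_shape=(16, 16),
        years=years,
        regions=[region],
        noise_sd=noise_sd,
    )
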