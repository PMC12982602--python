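"""Core in-memory containers shared across the pipeline.

The pipeline works on three kinds of gridded/tabular objects:

* :class:`LaiCube` — a leaf-area-index time series on a regular 500 m grid,
  organised as 8-day composites (46 per year by default) over several years;
* :class:`CropMask` — static boolean coverage per crop class plus an integer
  region partition of the same grid;
* :class:`HistoricalStats` — annual drought-impacted-area statistics per
  region and severity degree (thousand hectares), the calibration truth.

All rasters in one analysis share a single :class:`GridSpec` (north-up
affine transform, projected CRS identified by an EPSG code).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Crop season classes, in canonical processing order.
CROPS = ("summer", "autumn", "early_rice")

#: Severity degrees, from mildest to severest: drought-covered (yield loss
#: > 10%), drought-damaged (> 30%), crop failure (> 80%).
DEGREES = ("DC", "DD", "CF")

#: Raster code per degree in impact maps (99 = invalid / non-crop).
DEGREE_CODES = {"DC": 1, "DD": 2, "CF": 3}
INVALID_CODE = 99

#: File-name prefixes for the per-crop impact GeoTIFFs.
CROP_FILE_PREFIX = {"summer": "Summer", "autumn": "Autumn", "early_rice": "ER"}


class GridMismatchError(ValueError):
    """Two rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Regular north-up raster grid in a projected CRS.

    ``x_origin``/``y_origin`` are the coordinates of the outer corner of the
    top-left pixel; ``pixel_size`` is the square pixel edge in metres.
    """

    n_rows: int
    n_cols: int
    x_origin: float = 0.0
    y_origin: float = 0.0
    pixel_size: float = 500.0
    epsg: int = 32649  # UTM zone of the simulated study area

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid shape must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def transform(self) -> tuple[float, float, float, float, float, float]:
        """GDAL-style affine coefficients (a, b, c, d, e, f): x = a*col + c."""
        return (self.pixel_size, 0.0, self.x_origin, 0.0, -self.pixel_size, self.y_origin)

    @property
    def pixel_area_thousand_ha(self) -> float:
        """Ground area of one pixel in thousand hectares (0.025 at 500 m)."""
        return self.pixel_size**2 / 1e4 / 1e3

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of pixel centers, as 1-D column/row arrays."""
        xs = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        ys = self.y_origin - (np.arange(self.n_rows) + 0.5) * self.pixel_size
        return xs, ys

    def same_footprint(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.pixel_size, other.pixel_size)
            and self.epsg == other.epsg
        )


@dataclass
class LaiCube:
    """LAI values on ``grid`` indexed by (year, composite, row, col).

    ``values`` holds non-negative LAI where ``valid`` is True; entries with
    ``valid`` False are sentinels and must never enter a mean.
    """

    values: np.ndarray  # float32/float64, shape (n_years, n_composites, rows, cols)
    valid: np.ndarray  # bool, same shape
    years: tuple[int, ...]
    composite_doys: np.ndarray  # int, shape (n_composites,)
    grid: GridSpec

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        self.composite_doys = np.asarray(self.composite_doys, dtype=int)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask shapes differ")
        if self.values.shape[0] != len(self.years):
            raise ValueError("year axis does not match years list")
        if self.values.shape[1] != len(self.composite_doys):
            raise ValueError("composite axis does not match calendar")
        if self.values.shape[2:] != self.grid.shape:
            raise ValueError("spatial axes do not match grid")
        steps = np.diff(self.composite_doys)
        if len(steps) and (steps <= 0).any():
            raise ValueError("composite DOYs must be strictly increasing")

    @property
    def composite_step_days(self) -> int:
        return int(self.composite_doys[1] - self.composite_doys[0]) if len(self.composite_doys) > 1 else 365

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(int(year))
        except ValueError:
            raise KeyError(f"year {year} not in cube (has {self.years[0]}..{self.years[-1]})") from None

    def copy(self) -> "LaiCube":
        return LaiCube(
            values=self.values.copy(),
            valid=self.valid.copy(),
            years=self.years,
            composite_doys=self.composite_doys.copy(),
            grid=self.grid,
        )


@dataclass
class CropMask:
    """Per-crop boolean coverage plus an integer region partition.

    ``region_ids`` assigns each pixel to at most one region (0 = outside all
    regions); ``region_names`` maps the integer labels to region identifiers.
    A pixel may carry several crops (double cropping).
    """

    masks: dict[str, np.ndarray]  # crop -> bool (rows, cols)
    region_ids: np.ndarray  # int (rows, cols); 0 = no region
    region_names: dict[int, str]
    grid: GridSpec

    def __post_init__(self) -> None:
        for crop, m in self.masks.items():
            if crop not in CROPS:
                raise ValueError(f"unknown crop class {crop!r}")
            if m.shape != self.grid.shape:
                raise GridMismatchError(f"mask for {crop!r} does not match grid")
        if self.region_ids.shape != self.grid.shape:
            raise GridMismatchError("region raster does not match grid")

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.region_names[k] for k in sorted(self.region_names))

    def region_mask(self, region: str) -> np.ndarray:
        for label, name in self.region_names.items():
            if name == region:
                return self.region_ids == label
        raise KeyError(f"unknown region {region!r}")

    def crop_in_region(self, crop: str, region: str) -> np.ndarray:
        if crop not in self.masks:
            raise KeyError(f"no coverage mask for crop {crop!r}")
        return self.masks[crop] & self.region_mask(region)


class HistoricalStats:
    """Annual drought-impacted areas per (region, year, degree), thousand ha.

    Thin wrapper over a tidy DataFrame with columns
    ``region_id, year, degree, area_thousand_ha``.
    """

    COLUMNS = ("region_id", "year", "degree", "area_thousand_ha")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"stats table missing columns {sorted(missing)}")
        bad = set(frame["degree"].unique()) - set(DEGREES)
        if bad:
            raise ValueError(f"unknown severity degrees {sorted(bad)}")
        if (frame["area_thousand_ha"] < 0).any():
            raise ValueError("areas must be non-negative")
        self.frame = (
            frame.loc[:, list(self.COLUMNS)]
            .astype({"year": int, "area_thousand_ha": float})
            .sort_values(["region_id", "degree", "year"], kind="stable")
            .reset_index(drop=True)
        )

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, str, float]]) -> "HistoricalStats":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))

    @classmethod
    def read_csv(cls, path) -> "HistoricalStats":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["region_id"].unique()))

    def series(self, region: str, degree: str) -> pd.Series:
        """Area time series for one (region, degree), indexed by year."""
        sub = self.frame[(self.frame["region_id"] == region) & (self.frame["degree"] == degree)]
        if sub.empty:
            raise KeyError(f"no statistics for region {region!r}, degree {degree!r}")
        return sub.set_index("year")["area_thousand_ha"].sort_index()

    def value(self, region: str, year: int, degree: str) -> float:
        s = self.series(region, degree)
        if int(year) not in s.index:
            raise KeyError(f"no statistic for {region!r} {degree} in {year}")
        return float(s.loc[int(year)])
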