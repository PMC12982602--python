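"""Severity-coded impact rasters and the dataset file convention.

Each output raster holds one crop class, one severity degree, and one year.
Pixel codes: the degree's own code (1 drought-covered, 2 drought-damaged,
3 crop failure) where the threshold rule flags the pixel, 0 on assessed crop
pixels without impact at that degree, and 99 on non-crop or invalid pixels
(also the nodata value). Files follow ``{Crop}_{Degree}_{Year}.tif`` with
crop prefixes Summer / Autumn / ER.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import CalibrationResult
from .core import (
    CROP_FILE_PREFIX,
    DEGREE_CODES,
    DEGREES,
    INVALID_CODE,
    CropMask,
    GridSpec,
    GridMismatchError,
    LaiCube,
)
from .io import read_geotiff, write_geotiff
from .windows import window_mean

_PREFIX_TO_CROP = {v: k for k, v in CROP_FILE_PREFIX.items()}


@dataclass
class ImpactRaster:
    """Categorical per-pixel severity map for one (crop, degree, year)."""

    codes: np.ndarray  # uint8 (rows, cols), values in {0, degree code, 99}
    crop: str
    degree: str
    year: int
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.codes.shape != self.grid.shape:
            raise GridMismatchError("codes do not match grid")
        allowed = {0, DEGREE_CODES[self.degree], INVALID_CODE}
        found = set(np.unique(self.codes).tolist())
        if not found <= allowed:
            raise ValueError(f"codes {sorted(found - allowed)} not allowed for degree {self.degree}")

    @property
    def flagged(self) -> np.ndarray:
        return self.codes == DEGREE_CODES[self.degree]

    def area_thousand_ha(self) -> float:
        return float(self.flagged.sum()) * self.grid.pixel_area_thousand_ha


def classify(
    cube: LaiCube,
    masks: CropMask,
    calib: CalibrationResult,
    crop: str,
    degree: str,
    year: int,
) -> ImpactRaster:
    """Apply each region's calibrated (window, threshold) to one crop/degree/year.

    A crop pixel is flagged when its window-mean LAI is at most
    (T/100) x the baseline-year window-mean, with T and the window taken
    from the pixel's region. Crop pixels with invalid or zero baseline are
    coded 99, as are all non-crop pixels.
    """
    codes = np.full(cube.grid.shape, INVALID_CODE, dtype=np.uint8)
    code = DEGREE_CODES[degree]
    crop_regions = [
        region for region in masks.regions if masks.crop_in_region(crop, region).any()
    ]
    for region in crop_regions:
        entry = calib.entry(region, degree)  # raises if a region lacks calibration
        if crop not in entry.crops:
            raise KeyError(f"calibration for region {region!r}/{degree} lacks crop {crop!r}")
        fit = entry.crops[crop]
        mask = masks.crop_in_region(crop, region)
        actual = window_mean(cube, fit.window, year, mask)
        base = window_mean(cube, fit.window, entry.baseline_year, mask)
        valid = actual.valid & base.valid & (base.values > 0)
        flagged = valid & (actual.values <= (fit.t_percent / 100.0) * base.values)
        codes[valid] = 0
        codes[flagged] = code
    return ImpactRaster(codes=codes, crop=crop, degree=degree, year=int(year), grid=cube.grid)


@dataclass
class NestingReport:
    """Pixels flagged at a severer degree but not a milder one."""

    dd_not_dc: int
    cf_not_dd: int
    cf_not_dc: int

    @property
    def total_violations(self) -> int:
        return self.dd_not_dc + self.cf_not_dd + self.cf_not_dc


def check_nesting(
    dc: ImpactRaster,
    dd: ImpactRaster,
    cf: ImpactRaster,
    enforce: bool = False,
):
    """Verify (optionally enforce) CF ⊆ DD ⊆ DC on per-degree rasters.

    With ordered thresholds (T_CF <= T_DD <= T_DC) the flag sets nest by
    construction and the report is all-zero. In enforcement mode, milder
    flags are promoted wherever a severer flag exists, and the (possibly
    corrected) rasters are returned alongside the report of the original
    violations.
    """
    for a, b in ((dc, dd), (dd, cf)):
        if not a.grid.same_footprint(b.grid) or a.crop != b.crop or a.year != b.year:
            raise GridMismatchError("nesting check requires same crop, year, and grid")
    f_dc, f_dd, f_cf = dc.flagged, dd.flagged, cf.flagged
    report = NestingReport(
        dd_not_dc=int((f_dd & ~f_dc).sum()),
        cf_not_dd=int((f_cf & ~f_dd).sum()),
        cf_not_dc=int((f_cf & ~f_dc).sum()),
    )
    if not enforce:
        return report
    new_dd = dd.codes.copy()
    new_dc = dc.codes.copy()
    new_dd[f_cf] = DEGREE_CODES["DD"]
    new_dc[f_cf | f_dd] = DEGREE_CODES["DC"]
    dc2 = ImpactRaster(new_dc, dc.crop, "DC", dc.year, dc.grid)
    dd2 = ImpactRaster(new_dd, dd.crop, "DD", dd.year, dd.grid)
    return report, (dc2, dd2, cf)


def impact_filename(crop: str, degree: str, year: int) -> str:
    if degree not in DEGREES:
        raise ValueError(f"unknown degree {degree!r}")
    return f"{CROP_FILE_PREFIX[crop]}_{degree}_{int(year)}.tif"


def write_impact_tiff(raster: ImpactRaster, out_dir) -> Path:
    """Write one impact raster as ``{Crop}_{Degree}_{Year}.tif`` (nodata 99)."""
    out_dir = Path(out_dir)
    path = out_dir / impact_filename(raster.crop, raster.degree, raster.year)
    return write_geotiff(path, raster.codes, raster.grid, nodata=INVALID_CODE)


def read_impact_tiff(path) -> ImpactRaster:
    path = Path(path)
    m = re.fullmatch(r"(Summer|Autumn|ER)_(DC|DD|CF)_(\d{4})\.tif", path.name)
    if not m:
        raise ValueError(f"file name {path.name!r} does not follow the dataset convention")
    array, grid, _nodata = read_geotiff(path)
    return ImpactRaster(
        codes=array.astype(np.uint8),
        crop=_PREFIX_TO_CROP[m.group(1)],
        degree=m.group(2),
        year=int(m.group(3)),
        grid=grid,
    )


def merge_regions(rasters: list[ImpactRaster]) -> ImpactRaster:
    """Mosaic per-region rasters of one (crop, degree, year) on a shared grid.

    Pixels outside every region stay 99. Overlapping pixels must agree;
    conflicting non-99 codes raise.
    """
    if not rasters:
        raise ValueError("nothing to merge")
    first = rasters[0]
    codes = np.full(first.grid.shape, INVALID_CODE, dtype=np.uint8)
    for r in rasters:
        if not r.grid.same_footprint(first.grid) or (r.crop, r.degree, r.year) != (
            first.crop,
            first.degree,
            first.year,
        ):
            raise GridMismatchError("merge requires same crop, degree, year, and grid")
        data = r.codes != INVALID_CODE
        conflict = data & (codes != INVALID_CODE) & (codes != r.codes)
        if conflict.any():
            raise ValueError(f"{int(conflict.sum())} overlapping pixels with conflicting codes")
        codes[data] = r.codes[data]
    return ImpactRaster(codes, first.crop, first.degree, first.year, first.grid)


def area_summary(rasters: list[ImpactRaster], masks: CropMask) -> pd.DataFrame:
    """Flagged area per (region, crop, degree, year), thousand ha."""
    rows = []
    for r in rasters:
        for region in masks.regions:
            in_region = masks.region_mask(region)
            count = int((r.flagged & in_region).sum())
            if count or masks.crop_in_region(r.crop, region).any():
                rows.append(
                    (region, r.crop, r.degree, r.year, count * r.grid.pixel_area_thousand_ha)
                )
    return pd.DataFrame(
        rows, columns=["region_id", "crop", "degree", "year", "area_thousand_ha"]
    )
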