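"""Relative-threshold calibration against annual drought-area statistics.

For each (region, crop, severity degree) the method seeks the relative LAI
threshold ``T`` (percent of the baseline-year window-mean LAI) and the
candidate time window whose extracted annual areas best match the historical
statistics. A pixel is counted as impacted in year ``y`` when

    LAI_window_mean(y) <= (T / 100) * LAI_window_mean(baseline year)

and the extracted area is the flagged-pixel count times the pixel ground
area (0.025 thousand ha at 500 m). Per region and degree the estimated
series is the sum of per-crop extracted areas plus the historical area of
the baseline year; agreement with the historical series is scored by the
Pearson correlation R and the RMSE.

The threshold grid is the integer percentages 0..100. The selection rule for
"highest R and lowest RMSE" is lexicographic: maximise R, break ties by
minimal RMSE, then by smaller T, then by earlier window start, then by
shorter window — fully deterministic and order-independent.

Regions growing several crop classes are calibrated by coordinate descent
over crops (each sweep exhaustively re-optimises one crop's window and
threshold with the others held fixed), which reduces to the exhaustive
search for single-crop regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CROPS, DEGREES, CropMask, HistoricalStats, LaiCube
from .windows import TimeWindow, WindowMeanLai, enumerate_windows, season_composite_indices

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """A series needed for Pearson R has no variance."""


class CalibrationError(RuntimeError):
    """No admissible (window, threshold) candidate could be scored."""


# ---------------------------------------------------------------------------
# metric primitives
# ---------------------------------------------------------------------------


def pearson_r(ea: Sequence[float], ha: Sequence[float]) -> float:
    """Pearson product-moment correlation between two equal-length series.

    Raises :class:`ZeroVarianceError` when either series is constant; such
    candidates are excluded from threshold optimisation rather than scored.
    """
    ea = np.asarray(ea, dtype=float)
    ha = np.asarray(ha, dtype=float)
    if ea.shape != ha.shape:
        raise ValueError("series length mismatch")
    if ea.size < 3:
        raise ValueError("Pearson R requires at least 3 points")
    ea_c = ea - ea.mean()
    ha_c = ha - ha.mean()
    se = np.sqrt((ea_c**2).sum())
    sh = np.sqrt((ha_c**2).sum())
    if se == 0.0 or sh == 0.0:
        raise ZeroVarianceError("Pearson R undefined for a constant series")
    return float(np.clip((ea_c * ha_c).sum() / (se * sh), -1.0, 1.0))


def rmse(ea: Sequence[float], ha: Sequence[float]) -> float:
    """Root-mean-square error between two equal-length series (thousand ha)."""
    ea = np.asarray(ea, dtype=float)
    ha = np.asarray(ha, dtype=float)
    if ea.shape != ha.shape:
        raise ValueError("series length mismatch")
    if ea.size < 1:
        raise ValueError("RMSE requires at least 1 point")
    return float(np.sqrt(((ea - ha) ** 2).mean()))


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extracted_area(
    actual: WindowMeanLai,
    baseline: WindowMeanLai,
    t_percent: float,
    *,
    return_count: bool = False,
):
    """Drought-impacted area for one threshold, in thousand hectares.

    Counts valid crop pixels whose window-mean LAI is at most
    ``(t_percent / 100) * baseline`` (inclusive). Pixels invalid in either
    year, or with zero baseline LAI, are excluded entirely — a zero baseline
    would make the indicator degenerate and flag bare ground as drought.
    """
    if actual.values.shape != baseline.values.shape:
        raise ValueError("actual and baseline are on different pixel sets")
    if not 0.0 <= t_percent <= 100.0:
        raise ValueError("threshold must be in [0, 100] percent")
    valid = actual.valid & baseline.valid & (baseline.values > 0)
    flagged = valid & (actual.values <= (t_percent / 100.0) * baseline.values)
    count = int(flagged.sum())
    area = count * actual.pixel_area_thousand_ha
    if return_count:
        return area, count
    return area


def estimated_series(components: Mapping[str, pd.Series], ha_base: float) -> pd.Series:
    """Annual estimated areas: sum of per-crop extractions plus HA_base.

    All crop series must cover exactly the same years.
    """
    if not components:
        raise ValueError("no crop components given")
    series = {c: pd.Series(s).sort_index() for c, s in components.items()}
    idx = None
    for crop, s in series.items():
        if idx is None:
            idx = s.index
        elif not idx.equals(s.index):
            raise ValueError(f"crop {crop!r} series does not cover the same years")
    total = sum(series.values()) + float(ha_base)
    total.name = "EA_thousand_ha"
    return total


def select_baseline_year(stats: HistoricalStats, region: str) -> int:
    """Year with the weakest aggregate impact across all three degrees.

    The aggregate is the sum of the three degree areas; ties break to the
    earliest year. All three degree series must cover the same years.
    """
    series = {}
    for degree in DEGREES:
        try:
            series[degree] = stats.series(region, degree)
        except KeyError as exc:
            raise KeyError(f"region {region!r} lacks a {degree} series") from exc
    idx = series["DC"].index
    for degree in ("DD", "CF"):
        if not idx.equals(series[degree].index):
            raise ValueError(f"region {region!r} has incomplete degree series")
    total = sum(series.values()).sort_index()
    return int(total.index[int(np.argmin(total.values))])


# ---------------------------------------------------------------------------
# candidate tables
# ---------------------------------------------------------------------------


def _candidate_area_table(
    cube: LaiCube,
    crop_region_mask: np.ndarray,
    windows: Sequence[TimeWindow],
    baseline_year: int,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Extracted areas for every (window, year, threshold) candidate.

    Returns an array of shape (n_windows, n_years, n_thresholds) in thousand
    ha. Window means are computed with the same reduction as
    :func:`droughtlai.windows.window_mean` and the indicator uses the same
    inclusive comparison as :func:`extracted_area`, so candidate areas agree
    bit-for-bit with a direct extraction.
    """
    rows, cols = np.where(np.asarray(crop_region_mask, dtype=bool))
    n_pix = rows.size
    n_years = len(cube.years)
    n_t = len(t_grid)
    bi = cube.year_index(baseline_year)
    area_per_pixel = cube.grid.pixel_area_thousand_ha
    out = np.zeros((len(windows), n_years, n_t), dtype=float)
    if n_pix == 0:
        return out

    vals = cube.values[:, :, rows, cols].astype(float, copy=False)  # (Y, C, P)
    ok = cube.valid[:, :, rows, cols]
    w_vals = np.where(ok, vals, 0.0)

    t_frac = np.asarray(t_grid, dtype=float)
    for wi, w in enumerate(windows):
        sl = slice(w.start_index, w.end_index + 1)
        total = w_vals[:, sl, :].sum(axis=1)  # (Y, P)
        cnt = ok[:, sl, :].sum(axis=1)
        mean = np.zeros_like(total)
        np.divide(total, cnt, out=mean, where=cnt > 0)
        base = mean[bi]
        base_ok = (cnt[bi] > 0) & (base > 0)
        valid = (cnt > 0) & base_ok[None, :]

        # Smallest integer threshold flagging each pixel: start from
        # ceil(100 * ratio), then nudge by exact comparisons so the boundary
        # agrees bit-for-bit with `mean <= (T/100) * base`.
        with np.errstate(divide="ignore", invalid="ignore"):
            r100 = 100.0 * mean / base[None, :]
        tmin = np.ceil(np.where(valid, r100, np.inf))
        tmin = np.where(np.isfinite(tmin), tmin, 1000.0)
        safe_base = base[None, :]
        for _ in range(2):
            down = valid & (tmin > 0) & (mean <= ((tmin - 1.0) / 100.0) * safe_base)
            tmin = np.where(down, tmin - 1.0, tmin)
        for _ in range(2):
            up = valid & (tmin <= 100.0) & (mean > (tmin / 100.0) * safe_base)
            tmin = np.where(up, tmin + 1.0, tmin)
        tmin = np.where(valid, tmin, 1000.0)

        tmin.sort(axis=1)
        for yi in range(n_years):
            counts = np.searchsorted(tmin[yi], t_frac, side="right")
            out[wi, yi, :] = counts * area_per_pixel
    return out


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class CropFit:
    """Selected threshold and window for one crop within a degree calibration."""

    crop: str
    t_percent: int
    window: TimeWindow
    ea: np.ndarray  # per-year extracted areas, thousand ha


@dataclass
class DegreeCalibration:
    """Calibration outcome for one (region, degree)."""

    region: str
    degree: str
    baseline_year: int
    ha_base: float
    years: tuple[int, ...]
    ha: np.ndarray
    ea: np.ndarray
    r: float
    rmse: float
    crops: dict[str, CropFit]
    sweeps: int = 1


@dataclass
class CalibrationResult:
    """All per-(region, degree) calibrations, with tabular export."""

    entries: dict[tuple[str, str], DegreeCalibration] = field(default_factory=dict)

    def entry(self, region: str, degree: str) -> DegreeCalibration:
        try:
            return self.entries[(region, degree)]
        except KeyError:
            raise KeyError(f"no calibration for region {region!r}, degree {degree!r}") from None

    def table(self) -> pd.DataFrame:
        rows = []
        for (region, degree), e in sorted(self.entries.items()):
            for crop in sorted(e.crops, key=CROPS.index):
                fit = e.crops[crop]
                rows.append(
                    (
                        region,
                        crop,
                        degree,
                        fit.t_percent,
                        fit.window.start_doy,
                        fit.window.end_doy,
                        e.r,
                        e.rmse,
                        e.baseline_year,
                        e.ha_base,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "region_id",
                "crop",
                "degree",
                "t_percent",
                "window_start_doy",
                "window_end_doy",
                "r",
                "rmse",
                "baseline_year",
                "ha_base",
            ],
        )

    def series_table(self) -> pd.DataFrame:
        """Tidy EA-vs-HA series per (region, degree, year), for plots/validation."""
        rows = []
        for (region, degree), e in sorted(self.entries.items()):
            for year, ea_y, ha_y in zip(e.years, e.ea, e.ha):
                rows.append((region, degree, year, ea_y, ha_y))
        return pd.DataFrame(
            rows, columns=["region_id", "degree", "year", "ea_thousand_ha", "ha_thousand_ha"]
        )


# ---------------------------------------------------------------------------
# the grid search
# ---------------------------------------------------------------------------


def _score_candidates(ea: np.ndarray, ha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised R and RMSE of candidate series against the historical one.

    Candidates with zero variance get R = -inf so they are never selected.
    """
    ha_c = ha - ha.mean()
    sh = np.sqrt((ha_c**2).sum())
    if sh == 0.0:
        raise ZeroVarianceError("historical series is constant; R undefined for all candidates")
    ea_c = ea - ea.mean(axis=1, keepdims=True)
    se = np.sqrt((ea_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ea_c @ ha_c) / (se * sh)
    r = np.where(se > 0, r, -np.inf)
    rm = np.sqrt(((ea - ha) ** 2).mean(axis=1))
    return r, rm


def _select_candidate(
    r: np.ndarray,
    rm: np.ndarray,
    t_vals: np.ndarray,
    w_start: np.ndarray,
    w_len: np.ndarray,
) -> int:
    if not np.isfinite(r).any():
        raise CalibrationError(
            "every candidate produced a zero-variance estimated series; "
            "the historical statistics cannot constrain the threshold"
        )
    # Quantise the scores for ordering so that candidates whose R/RMSE agree
    # up to floating-point noise fall through to the deterministic
    # tie-breaks (smaller T, earlier then shorter window).
    r_q = np.round(r, 9)
    rm_q = np.round(rm, 9)
    order = np.lexsort((w_len, w_start, t_vals, rm_q, -r_q))
    return int(order[0])


def calibrate_degree(
    cube: LaiCube,
    masks: CropMask,
    stats: HistoricalStats,
    region: str,
    degree: str,
    windows_per_crop: Mapping[str, Sequence[TimeWindow]],
    baseline_year: int,
    t_grid: Sequence[int] | None = None,
    max_sweeps: int = 10,
) -> DegreeCalibration:
    """Grid-search threshold and window for one (region, degree).

    Single-crop regions are solved by exhaustive search over
    (window x threshold); multi-crop regions by deterministic coordinate
    descent over crops in canonical order, each sweep exhaustive for one
    crop with the others held fixed.
    """
    if not windows_per_crop:
        raise ValueError("no candidate windows supplied")
    t_grid = np.arange(0, 101, dtype=int) if t_grid is None else np.asarray(t_grid, dtype=int)
    if t_grid.size == 0 or t_grid.min() < 0 or t_grid.max() > 100:
        raise ValueError("threshold grid must lie within [0, 100]")

    ha_series = stats.series(region, degree)
    years = cube.years
    missing = [y for y in years if y not in ha_series.index]
    if missing:
        raise ValueError(f"historical series for {region!r}/{degree} lacks years {missing}")
    ha = ha_series.loc[list(years)].to_numpy(dtype=float)
    if baseline_year not in years:
        raise KeyError(f"baseline year {baseline_year} not in cube years")
    ha_base = float(ha_series.loc[baseline_year])

    crops = sorted(windows_per_crop, key=CROPS.index)
    tables: dict[str, np.ndarray] = {}
    metas: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for crop in crops:
        wins = list(windows_per_crop[crop])
        if not wins:
            raise ValueError(f"empty candidate window list for crop {crop!r}")
        mask = masks.crop_in_region(crop, region)
        tables[crop] = _candidate_area_table(cube, mask, wins, baseline_year, t_grid)
        n_w = len(wins)
        w_start = np.repeat([w.start_doy for w in wins], t_grid.size)
        w_len = np.repeat([w.n_composites for w in wins], t_grid.size)
        t_vals = np.tile(t_grid, n_w)
        metas[crop] = (t_vals, w_start, w_len)

    n_years = len(years)

    # current state: per crop (window index, threshold index)
    state: dict[str, tuple[int, int]] = {}
    for crop in crops:
        wins = list(windows_per_crop[crop])
        full = max(range(len(wins)), key=lambda i: wins[i].n_composites)
        state[crop] = (full, int(t_grid.size - 1))

    def crop_ea(crop: str) -> np.ndarray:
        wi, ti = state[crop]
        return tables[crop][wi, :, ti]

    sweeps = 0
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        changed = False
        for crop in crops:
            other = sum((crop_ea(c) for c in crops if c != crop), np.zeros(n_years))
            tab = tables[crop]  # (W, Y, T)
            cand = tab.transpose(0, 2, 1).reshape(-1, n_years) + other + ha_base
            r, rm = _score_candidates(cand, ha)
            t_vals, w_start, w_len = metas[crop]
            k = _select_candidate(r, rm, t_vals, w_start, w_len)
            wi, ti = divmod(k, t_grid.size)
            if state[crop] != (wi, ti):
                state[crop] = (wi, ti)
                changed = True
        if not changed:
            break
    if len(crops) > 1:
        logger.info(
            "region %s degree %s: coordinate descent over %d crops converged in %d sweep(s)",
            region,
            degree,
            len(crops),
            sweeps,
        )

    ea_total = sum((crop_ea(c) for c in crops), np.zeros(n_years)) + ha_base
    r_final, rm_final = _score_candidates(ea_total[None, :], ha)
    fits = {}
    for crop in crops:
        wi, ti = state[crop]
        fits[crop] = CropFit(
            crop=crop,
            t_percent=int(t_grid[ti]),
            window=list(windows_per_crop[crop])[wi],
            ea=tables[crop][wi, :, ti].copy(),
        )
    return DegreeCalibration(
        region=region,
        degree=degree,
        baseline_year=int(baseline_year),
        ha_base=ha_base,
        years=tuple(years),
        ha=ha,
        ea=ea_total,
        r=float(r_final[0]),
        rmse=float(rm_final[0]),
        crops=fits,
        sweeps=sweeps,
    )


def calibrate_all(
    cube: LaiCube,
    masks: CropMask,
    stats: HistoricalStats,
    seasons: Mapping[str, Mapping[str, tuple[int, int]]],
    baseline_years: Mapping[str, int] | None = None,
    t_grid: Sequence[int] | None = None,
    degrees: Sequence[str] = DEGREES,
) -> CalibrationResult:
    """Calibrate every (region, degree) in ``seasons``.

    ``seasons`` maps region -> crop -> (doy_start, doy_end) growing season.
    Baseline years are auto-selected from the statistics unless overridden.
    """
    step = cube.composite_step_days
    result = CalibrationResult()
    for region, crop_seasons in seasons.items():
        if baseline_years and region in baseline_years:
            base_year = int(baseline_years[region])
        else:
            base_year = select_baseline_year(stats, region)
        windows_per_crop = {
            crop: enumerate_windows(ds, de, step) for crop, (ds, de) in crop_seasons.items()
        }
        for degree in degrees:
            entry = calibrate_degree(
                cube, masks, stats, region, degree, windows_per_crop, base_year, t_grid
            )
            result.entries[(region, degree)] = entry
            logger.info(
                "calibrated %s/%s: R=%.3f RMSE=%.3f, %s",
                region,
                degree,
                entry.r,
                entry.rmse,
                {c: (f.t_percent, (f.window.start_doy, f.window.end_doy)) for c, f in entry.crops.items()},
            )
    return result
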