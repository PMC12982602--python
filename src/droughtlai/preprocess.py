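"""Pre-processing: Savitzky–Golay smoothing, fill masking, grid alignment.

Smoothing is applied per pixel per year over that year's composite series,
never across year boundaries. The stated defaults (window 3, polynomial
order 3) are degenerate — a cubic through three points is underdetermined —
so the order is clamped to window - 1 with a warning; note that SG with
order = window - 1 interpolates and is therefore the identity, i.e. the
default configuration performs no numerical smoothing. Larger windows give
genuine smoothing.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import savgol_filter

from .core import GridSpec, LaiCube

DEFAULT_SG_WINDOW = 3
DEFAULT_SG_POLYORDER = 3  # clamped to window - 1 at call time


def _clamp_polyorder(window_length: int, polyorder: int) -> int:
    if window_length % 2 == 0 or window_length < 3:
        raise ValueError("window_length must be an odd integer >= 3")
    if polyorder < 0:
        raise ValueError("polyorder must be non-negative")
    if polyorder >= window_length:
        clamped = window_length - 1
        warnings.warn(
            f"Savitzky-Golay polyorder {polyorder} >= window {window_length} is "
            f"underdetermined; clamping to {clamped}",
            UserWarning,
            stacklevel=3,
        )
        return clamped
    return polyorder


def sg_smooth(
    series: np.ndarray,
    window_length: int = DEFAULT_SG_WINDOW,
    polyorder: int = DEFAULT_SG_POLYORDER,
    axis: int = -1,
) -> np.ndarray:
    """Savitzky–Golay least-squares local-polynomial smoothing.

    The series length is preserved; at the endpoints the filter fits a
    single polynomial to the first/last window and evaluates it there, so
    polynomials of degree <= polyorder are reproduced exactly everywhere
    (mirror padding would break this at the edges).
    """
    series = np.asarray(series, dtype=float)
    polyorder = _clamp_polyorder(window_length, polyorder)
    if series.shape[axis] < window_length:
        raise ValueError(
            f"series length {series.shape[axis]} shorter than window {window_length}"
        )
    if polyorder == window_length - 1:
        # the interpolating configuration: the fitted polynomial passes
        # through every point, so the filter is exactly the identity —
        # return it as such rather than through numerically-solved
        # coefficients that would perturb the data at the ulp level
        return series.copy()
    return savgol_filter(series, window_length, polyorder, axis=axis, mode="interp")


def smooth_cube(
    cube: LaiCube,
    window_length: int = DEFAULT_SG_WINDOW,
    polyorder: int = DEFAULT_SG_POLYORDER,
) -> LaiCube:
    """Smooth every pixel's yearly composite series; invalid entries stay invalid.

    Pixels with gaps are linearly interpolated across the invalid composites
    before filtering so the fit is not biased by sentinels; the validity mask
    is unchanged, so interpolated positions never enter window means.
    """
    out = cube.copy()
    n_years = len(cube.years)
    x = np.arange(len(cube.composite_doys))
    for yi in range(n_years):
        vals = out.values[yi]  # (C, rows, cols)
        ok = out.valid[yi]
        if not ok.all():
            bad_pix = np.where(~ok.all(axis=0))
            for r, c in zip(*bad_pix):
                good = ok[:, r, c]
                if good.sum() == 0:
                    continue  # nothing to smooth; stays fully invalid
                vals[:, r, c] = np.interp(x, x[good], vals[good, r, c])
        out.values[yi] = sg_smooth(vals, window_length, polyorder, axis=0)
    return out


def mask_invalid(cube: LaiCube, fill_values: set[float] | frozenset[float]) -> LaiCube:
    """Mark entries holding any of the sentinel fill codes as invalid.

    Valid values are never altered; masking only removes entries from
    consideration in smoothing and window means.
    """
    out = cube.copy()
    if fill_values:
        fills = np.asarray(sorted(fill_values), dtype=float)
        out.valid &= ~np.isin(out.values, fills)
    return out


def align_nearest(
    raster: np.ndarray,
    source_grid: GridSpec,
    target_grid: GridSpec,
    fill=np.nan,
) -> np.ndarray:
    """Nearest-neighbour resampling of a single-band raster onto a target grid.

    Each target pixel takes the value of the source pixel containing its
    center; categorical values are never interpolated. Target pixels whose
    center lies outside the source extent receive ``fill``. Both grids must
    share the same CRS — reprojection is out of scope.
    """
    raster = np.asarray(raster)
    if raster.shape != source_grid.shape:
        raise ValueError("raster shape does not match source grid")
    if source_grid.epsg != target_grid.epsg:
        raise ValueError(
            f"CRS mismatch (EPSG:{source_grid.epsg} vs EPSG:{target_grid.epsg}); "
            "reproject before aligning"
        )
    xs, ys = target_grid.pixel_centers()
    cols = np.floor((xs - source_grid.x_origin) / source_grid.pixel_size).astype(int)
    rows = np.floor((source_grid.y_origin - ys) / source_grid.pixel_size).astype(int)
    col_ok = (cols >= 0) & (cols < source_grid.n_cols)
    row_ok = (rows >= 0) & (rows < source_grid.n_rows)
    out = np.full(target_grid.shape, fill, dtype=np.result_type(raster.dtype, type(fill)))
    rr = np.clip(rows, 0, source_grid.n_rows - 1)
    cc = np.clip(cols, 0, source_grid.n_cols - 1)
    vals = raster[np.ix_(rr, cc)]
    inside = np.outer(row_ok, col_ok)
    out[inside] = vals[inside]
    return out
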