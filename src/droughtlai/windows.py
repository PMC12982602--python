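"""Candidate phenological time windows and per-pixel window-mean LAI.

Candidate windows are contiguous runs of 8-day composites inside a crop's
growing season; the calibration stage searches them jointly with the relative
threshold. A season spanning ``m`` composites yields ``m (m + 1) / 2``
candidates (e.g. DOY 145–273 at 8-day steps: m = 17, 153 windows). Windows
are computational constructs, not agronomic stages; the one selected by
calibration is reported as the key phenological period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LaiCube


def composite_calendar(step_days: int = 8) -> np.ndarray:
    """DOY-anchored composite start days: 1, 1+step, … ≤ 365.

    Follows the MODIS 8-day convention (46 composites per year); leap day
    366 is never a composite start.
    """
    if step_days < 1:
        raise ValueError("step_days must be >= 1")
    return np.arange(1, 366, step_days, dtype=int)


@dataclass(frozen=True, order=True)
class TimeWindow:
    """Inclusive run [start_index, end_index] of composites, with DOY bounds."""

    start_index: int
    end_index: int
    start_doy: int
    end_doy: int

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("window start after end")

    @property
    def n_composites(self) -> int:
        return self.end_index - self.start_index + 1


def season_composite_indices(doy_start: int, doy_end: int, step_days: int = 8) -> np.ndarray:
    """Indices (into the composite calendar) falling inside [doy_start, doy_end].

    Bounds not on the calendar are snapped inward (start up, end down) so all
    windows stay inside the declared season.
    """
    if doy_start > doy_end:
        raise ValueError("season start after end")
    if not (1 <= doy_start and doy_end <= 365):
        raise ValueError("season bounds must lie in [1, 365]")
    cal = composite_calendar(step_days)
    idx = np.where((cal >= doy_start) & (cal <= doy_end))[0]
    if idx.size == 0:
        raise ValueError(
            f"no composites in season DOY {doy_start}-{doy_end} at step {step_days}"
        )
    return idx


def enumerate_windows(doy_start: int, doy_end: int, step_days: int = 8) -> list[TimeWindow]:
    """All contiguous composite runs inside the season, in canonical order.

    Ordered by start index then end index; count = m(m+1)/2 for m composites.
    """
    cal = composite_calendar(step_days)
    idx = season_composite_indices(doy_start, doy_end, step_days)
    out: list[TimeWindow] = []
    for a in range(len(idx)):
        for b in range(a, len(idx)):
            i, j = int(idx[a]), int(idx[b])
            out.append(TimeWindow(i, j, int(cal[i]), int(cal[j])))
    return out


@dataclass
class WindowMeanLai:
    """Per-pixel mean LAI over one window, year, and crop mask.

    ``values`` is defined (and ``valid`` True) only on crop pixels with at
    least one valid composite inside the window.
    """

    values: np.ndarray  # float, (rows, cols); undefined where ~valid
    valid: np.ndarray  # bool, (rows, cols)
    year: int
    window: TimeWindow
    pixel_area_thousand_ha: float = 0.025

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("values/valid shape mismatch")


def window_mean(cube: LaiCube, window: TimeWindow, year: int, crop_mask: np.ndarray) -> WindowMeanLai:
    """Arithmetic mean of valid LAI composites inside ``window`` for ``year``.

    Non-crop pixels and crop pixels with zero valid composites in the window
    are flagged invalid (excluded from any downstream extraction).
    """
    yi = cube.year_index(year)
    if not (0 <= window.start_index and window.end_index < len(cube.composite_doys)):
        raise ValueError("window outside cube composite calendar")
    crop_mask = np.asarray(crop_mask, dtype=bool)
    if crop_mask.shape != cube.grid.shape:
        raise ValueError("crop mask does not match cube grid")

    sl = slice(window.start_index, window.end_index + 1)
    vals = cube.values[yi, sl]
    ok = cube.valid[yi, sl]
    cnt = ok.sum(axis=0)
    total = np.where(ok, vals, 0.0).sum(axis=0)
    valid = crop_mask & (cnt > 0)
    means = np.zeros(cube.grid.shape, dtype=float)
    np.divide(total, cnt, out=means, where=cnt > 0)
    return WindowMeanLai(
        values=means,
        valid=valid,
        year=int(year),
        window=window,
        pixel_area_thousand_ha=cube.grid.pixel_area_thousand_ha,
    )


def windows_to_frame(windows_by_key: dict) -> "object":
    """Serialize candidate window lists to a tidy table for logging.

    ``windows_by_key`` maps (region, crop) -> list[TimeWindow].
    """
    import pandas as pd

    rows = []
    for (region, crop), wins in windows_by_key.items():
        for w in wins:
            rows.append((region, crop, w.start_doy, w.end_doy))
    return pd.DataFrame(rows, columns=["region_id", "crop", "start_doy", "end_doy"])
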