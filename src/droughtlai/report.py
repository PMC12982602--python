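"""Validation tables: EA-vs-HA consistency metrics and recovery summaries.

All metrics go through the calibrate module's :func:`pearson_r` and
:func:`rmse` so that reported numbers are exactly the quantities the
optimisation scored — no reimplementation drift.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calibrate as _cal
from .calibrate import CalibrationResult, ZeroVarianceError
from .core import CROPS, DEGREES, HistoricalStats
from .synthetic import SyntheticTruth

# shared code path with the optimisation — asserted by test
pearson_r = _cal.pearson_r
rmse = _cal.rmse

POOLED_LABEL = "__pooled__"


def validate_series(calib: CalibrationResult, stats: HistoricalStats) -> pd.DataFrame:
    """R and RMSE per (region, degree), plus pooled rows per degree.

    Pooled metrics concatenate all (region, year) pairs of a degree rather
    than averaging per-region metrics, matching how scatter-plot pooling
    treats regions. R is NaN where undefined (constant series or < 3 years).
    """
    keys = [
        (region, degree)
        for (region, degree) in calib.entries
        if _has_series(stats, region, degree)
    ]
    if not keys:
        raise ValueError("no overlapping (region, degree) keys between calibration and stats")

    rows = []
    pooled: dict[str, tuple[list[float], list[float]]] = {d: ([], []) for d in DEGREES}
    for region, degree in sorted(keys):
        entry = calib.entries[(region, degree)]
        ha = stats.series(region, degree).loc[list(entry.years)].to_numpy(dtype=float)
        ea = np.asarray(entry.ea, dtype=float)
        rows.append((region, degree, len(entry.years), _safe_r(ea, ha), rmse(ea, ha)))
        pooled[degree][0].extend(ea.tolist())
        pooled[degree][1].extend(ha.tolist())
    for degree in DEGREES:
        ea, ha = pooled[degree]
        if ea:
            rows.append(
                (POOLED_LABEL, degree, len(ea), _safe_r(np.array(ea), np.array(ha)), rmse(ea, ha))
            )
    return pd.DataFrame(
        rows, columns=["region_id", "degree", "n_years", "r", "rmse_thousand_ha"]
    )


def _has_series(stats: HistoricalStats, region: str, degree: str) -> bool:
    try:
        stats.series(region, degree)
        return True
    except KeyError:
        return False


def _safe_r(ea: np.ndarray, ha: np.ndarray) -> float:
    try:
        return pearson_r(ea, ha)
    except (ZeroVarianceError, ValueError):
        return float("nan")


def recovery_summary(truth: SyntheticTruth, calib: CalibrationResult) -> pd.DataFrame:
    """Parameter-recovery table per (region, crop, degree).

    Columns: recovered and true thresholds, their difference, whether the
    recovered window matches the truth window, and the achieved R / RMSE of
    the degree calibration.
    """
    rows = []
    for (region, degree), entry in sorted(calib.entries.items()):
        for crop in sorted(entry.crops, key=CROPS.index):
            fit = entry.crops[crop]
            t_true = truth.thresholds[(region, crop, degree)]
            w_true = truth.windows[(region, crop)]
            rows.append(
                (
                    region,
                    crop,
                    degree,
                    fit.t_percent,
                    t_true,
                    fit.t_percent - t_true,
                    fit.window.start_doy == w_true.start_doy
                    and fit.window.end_doy == w_true.end_doy,
                    entry.r,
                    entry.rmse,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "crop",
            "degree",
            "t_recovered",
            "t_true",
            "t_error",
            "window_match",
            "r",
            "rmse_thousand_ha",
        ],
    )


def plot_ea_vs_ha(calib: CalibrationResult, path=None):
    """Scatter of estimated vs historical areas per degree (one panel each)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    series = calib.series_table()
    fig, axes = plt.subplots(1, len(DEGREES), figsize=(4 * len(DEGREES), 4))
    for ax, degree in zip(np.atleast_1d(axes), DEGREES):
        sub = series[series["degree"] == degree]
        ax.scatter(sub["ha_thousand_ha"], sub["ea_thousand_ha"], s=12)
        lim = max(sub["ha_thousand_ha"].max(), sub["ea_thousand_ha"].max(), 1.0)
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("historical area (thousand ha)")
        ax.set_ylabel("estimated area (thousand ha)")
        ax.set_title(degree)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
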