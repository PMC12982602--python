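"""Baseline selection, extraction, metrics, and the threshold grid search."""

import numpy as np
import pandas as pd
import pytest

import droughtlai as dl
from droughtlai.calibrate import (
    CalibrationError,
    ZeroVarianceError,
    calibrate_degree,
    estimated_series,
    extracted_area,
    pearson_r,
    rmse,
    select_baseline_year,
)
from droughtlai.core import HistoricalStats
from droughtlai.synthetic import DroughtEvent
from droughtlai.windows import TimeWindow, WindowMeanLai, enumerate_windows
from conftest import small_config, small_region


def wml(values, valid=None, **kw):
    values = np.asarray(values, dtype=float)
    valid = np.ones_like(values, bool) if valid is None else np.asarray(valid, bool)
    return WindowMeanLai(values=values, valid=valid, year=2000, window=TimeWindow(0, 0, 1, 1), **kw)


def brute_force_area(actual, baseline, t):
    count = 0
    for a, b, va, vb in zip(
        actual.values.ravel(), baseline.values.ravel(), actual.valid.ravel(), baseline.valid.ravel()
    ):
        if va and vb and b > 0 and a <= (t / 100.0) * b:
            count += 1
    return count * 0.025


class TestSelectBaselineYear:
    def _stats(self, table):
        recs = [
            (r, y, d, a)
            for (r, y), degs in table.items()
            for d, a in zip(("DC", "DD", "CF"), degs)
        ]
        return HistoricalStats.from_records(recs)

    def test_all_zero_year_wins(self):
        stats = self._stats({("p", 2010): (5, 3, 1), ("p", 2011): (0, 0, 0), ("p", 2012): (9, 2, 1)})
        assert select_baseline_year(stats, "p") == 2011

    def test_minimal_sum_wins(self):
        stats = self._stats(
            {("p", 2010): (100, 50, 10), ("p", 2011): (80, 40, 5), ("p", 2012): (90, 60, 20)}
        )
        assert select_baseline_year(stats, "p") == 2011

    def test_tie_breaks_to_earlier_year(self):
        stats = self._stats({("p", 2010): (10, 5, 0), ("p", 2011): (5, 5, 5), ("p", 2012): (20, 1, 1)})
        assert select_baseline_year(stats, "p") == 2010

    def test_missing_degree_series_rejected(self):
        stats = HistoricalStats.from_records([("p", 2010, "DC", 1.0), ("p", 2010, "DD", 1.0)])
        with pytest.raises(KeyError, match="CF"):
            select_baseline_year(stats, "p")


class TestExtractedArea:
    def test_worked_example(self):
        actual = wml([1.0, 2.0, 3.0, 4.0])
        base = wml([2.0, 2.0, 2.0, 2.0])
        assert extracted_area(actual, base, 50) == pytest.approx(0.025)

    def test_zero_threshold_flags_nothing_positive(self):
        actual = wml([1.0, 2.0])
        assert extracted_area(actual, wml([2.0, 2.0]), 0) == 0.0

    def test_full_threshold_counts_all_on_equality(self):
        base = wml([1.5, 2.5, 3.5])
        assert extracted_area(base, base, 100) == pytest.approx(3 * 0.025)

    def test_zero_or_invalid_baseline_excluded(self):
        actual = wml([0.0, 1.0, 1.0])
        base = wml([0.0, 2.0, 2.0], valid=[True, True, False])
        assert extracted_area(actual, base, 100) == pytest.approx(0.025)

    def test_mismatched_pixel_sets_rejected(self):
        with pytest.raises(ValueError, match="pixel sets"):
            extracted_area(wml([1.0]), wml([1.0, 2.0]), 50)

    def test_matches_brute_force_on_random_grids(self, rng):
        for _ in range(20):
            shape = (rng.integers(1, 11), rng.integers(1, 11))
            actual = wml(rng.random(shape) * 4, rng.random(shape) > 0.1)
            base = wml(rng.random(shape) * 4, rng.random(shape) > 0.1)
            t = int(rng.integers(0, 101))
            assert extracted_area(actual, base, t) == pytest.approx(
                brute_force_area(actual, base, t)
            )

    def test_nondecreasing_in_threshold(self, rng):
        actual = wml(rng.random((8, 8)) * 4)
        base = wml(rng.random((8, 8)) * 4)
        areas = [extracted_area(actual, base, t) for t in range(101)]
        assert all(b >= a for a, b in zip(areas, areas[1:]))


class TestEstimatedSeries:
    def test_elementwise_sum_plus_base(self):
        ea = estimated_series(
            {"summer": pd.Series([1.0, 2.0], index=[2006, 2007]),
             "autumn": pd.Series([3.0, 4.0], index=[2006, 2007])},
            ha_base=10.0,
        )
        assert list(ea) == [14.0, 16.0]

    def test_zero_components_zero_base(self):
        ea = estimated_series({"summer": pd.Series([0.0, 0.0], index=[2006, 2007])}, 0.0)
        assert (ea == 0).all()

    def test_missing_year_rejected(self):
        with pytest.raises(ValueError, match="same years"):
            estimated_series(
                {"summer": pd.Series([1.0], index=[2006]),
                 "autumn": pd.Series([1.0, 2.0], index=[2006, 2007])},
                0.0,
            )


class TestMetrics:
    def test_identity_gives_r_one(self):
        assert pearson_r([1, 2, 4], [1, 2, 4]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        ea, ha = np.array([1.0, 2.0, 4.0]), np.array([2.0, 3.0, 9.0])
        num = ((ea - ea.mean()) * (ha - ha.mean())).sum()
        den = np.sqrt(((ea - ea.mean()) ** 2).sum()) * np.sqrt(((ha - ha.mean()) ** 2).sum())
        assert pearson_r(ea, ha) == pytest.approx(num / den)

    def test_zero_variance_flagged(self):
        with pytest.raises(ZeroVarianceError):
            pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ZeroVarianceError):
            pearson_r([1, 2, 3], [5, 5, 5])

    def test_rmse_examples(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([1.0, 2.0], [2.0, 4.0]) == pytest.approx(np.sqrt(2.5))

    def test_rmse_homogeneity(self, rng):
        ea, ha = rng.random(10), rng.random(10)
        assert rmse(3.5 * ea, 3.5 * ha) == pytest.approx(3.5 * rmse(ea, ha))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0, 3.0], [1.0, 2.0])


class TestCalibrateDegree:
    def test_noise_free_recovery_single_region(self):
        cfg = dl.single_region_scenario(seed=9, stats_noise_cv=0.0)
        cube, masks, truth = dl.generate_lai_cube(cfg)
        stats = dl.derive_historical_stats(cube, masks, truth, 0.0)
        calib = dl.calibrate_all(cube, masks, stats, truth.seasons)
        for degree in ("DC", "DD", "CF"):
            e = calib.entry("plain", degree)
            assert e.r == pytest.approx(1.0)
            assert e.rmse == pytest.approx(0.0, abs=1e-9)
            assert e.crops["autumn"].t_percent == truth.thresholds[("plain", "autumn", degree)]
            assert np.allclose(e.ea, e.ha, atol=1e-9)

    def test_constant_statistics_rejected(self):
        cube, masks, truth = dl.generate_lai_cube(small_config())
        recs = [("r1", y, d, 5.0) for y in cube.years for d in ("DC", "DD", "CF")]
        stats = HistoricalStats.from_records(recs)
        wins = enumerate_windows(145, 273, 8)
        with pytest.raises(ZeroVarianceError, match="constant"):
            calibrate_degree(cube, masks, stats, "r1", "DC", {"autumn": wins}, 2006)

    def test_deterministic_across_runs(self):
        cfg = dl.single_region_scenario(seed=21)
        cube, masks, truth = dl.generate_lai_cube(cfg)
        stats = dl.derive_historical_stats(cube, masks, truth, cfg.stats_noise_cv)
        a = dl.calibrate_all(cube, masks, stats, truth.seasons).table()
        b = dl.calibrate_all(cube, masks, stats, truth.seasons).table()
        pd.testing.assert_frame_equal(a, b)

    def test_selected_series_dominates_truth_candidate(self):
        """The lexicographic selection never returns a candidate worse than
        the truth parameters themselves."""
        cfg = dl.single_region_scenario(seed=33)  # noisy stats
        cube, masks, truth = dl.generate_lai_cube(cfg)
        stats = dl.derive_historical_stats(cube, masks, truth, cfg.stats_noise_cv)
        calib = dl.calibrate_all(cube, masks, stats, truth.seasons)
        for degree in ("DC", "DD", "CF"):
            e = calib.entry("plain", degree)
            ha = stats.series("plain", degree).loc[list(e.years)].to_numpy()
            truth_ea = np.array(
                [truth.true_areas[("plain", y, degree)] for y in e.years]
            ) + e.ha_base
            assert e.r >= pearson_r(truth_ea, ha) - 1e-9

    def test_multi_crop_coordinate_descent(self):
        cfg = dl.double_cropping_scenario(seed=3)
        cube, masks, truth = dl.generate_lai_cube(cfg)
        stats = dl.derive_historical_stats(cube, masks, truth, 0.0)
        calib = dl.calibrate_all(cube, masks, stats, truth.seasons)
        for degree in ("DC", "DD"):
            e = calib.entry("valley", degree)
            for crop in ("summer", "autumn"):
                assert e.crops[crop].t_percent == truth.thresholds[("valley", crop, degree)]
        for degree in ("DC", "DD", "CF"):
            e = calib.entry("valley", degree)
            assert e.r >= 0.99
            assert e.sweeps <= 10
        # double cropping: shared pixels carry both crop masks
        assert (masks.masks["summer"] & masks.masks["autumn"]).any()
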