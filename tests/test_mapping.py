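"""Impact raster classification, nesting, file convention, mosaics."""

import numpy as np
import pytest

import droughtlai as dl
from droughtlai.calibrate import extracted_area
from droughtlai.mapping import (
    ImpactRaster,
    area_summary,
    check_nesting,
    classify,
    impact_filename,
    merge_regions,
    read_impact_tiff,
    write_impact_tiff,
)
from droughtlai.core import INVALID_CODE
from droughtlai.windows import window_mean


@pytest.fixture(scope="module")
def classified(two_region_run_mod, two_region_calibration_mod):
    cfg, cube, masks, truth, stats = two_region_run_mod
    calib = two_region_calibration_mod
    return cube, masks, calib


@pytest.fixture(scope="module")
def two_region_run_mod():
    cfg = dl.two_region_scenario(seed=11)
    cube, masks, truth = dl.generate_lai_cube(cfg)
    stats = dl.derive_historical_stats(cube, masks, truth, 0.0)
    return cfg, cube, masks, truth, stats


@pytest.fixture(scope="module")
def two_region_calibration_mod(two_region_run_mod):
    cfg, cube, masks, truth, stats = two_region_run_mod
    return dl.calibrate_all(cube, masks, stats, truth.seasons)


class TestClassify:
    def test_area_consistent_with_extraction(self, classified):
        cube, masks, calib = classified
        for degree in ("DC", "DD", "CF"):
            raster = classify(cube, masks, calib, "autumn", degree, 2014)
            e = calib.entry("south", degree)
            fit = e.crops["autumn"]
            mask = masks.crop_in_region("autumn", "south")
            actual = window_mean(cube, fit.window, 2014, mask)
            base = window_mean(cube, fit.window, e.baseline_year, mask)
            expect = extracted_area(actual, base, fit.t_percent)
            got = (raster.flagged & masks.region_mask("south")).sum() * 0.025
            assert got == pytest.approx(expect)

    def test_baseline_year_unflagged(self, classified):
        cube, masks, calib = classified
        raster = classify(cube, masks, calib, "autumn", "DC", 2006)
        assert raster.flagged.sum() == 0

    def test_non_crop_pixels_are_invalid_code(self, classified):
        cube, masks, calib = classified
        raster = classify(cube, masks, calib, "summer", "DC", 2009)
        assert (raster.codes[~masks.masks["summer"]] == INVALID_CODE).all()
        assert set(np.unique(raster.codes)) <= {0, 1, INVALID_CODE}

    def test_missing_region_calibration_rejected(self, classified):
        cube, masks, _ = classified
        empty = dl.CalibrationResult()
        with pytest.raises(KeyError, match="no calibration"):
            classify(cube, masks, empty, "autumn", "DC", 2014)


class TestNesting:
    def _rasters(self, classified, year=2014):
        cube, masks, calib = classified
        return {
            d: classify(cube, masks, calib, "autumn", d, year) for d in ("DC", "DD", "CF")
        }

    def test_ordered_thresholds_nest(self, classified):
        r = self._rasters(classified)
        rep = check_nesting(r["DC"], r["DD"], r["CF"])
        assert rep.total_violations == 0

    def test_swapped_thresholds_violate_and_enforcement_fixes(self, classified):
        r = self._rasters(classified)
        # swap: present CF flags where DC has none, by crafting rasters
        dc = r["DC"]
        cf_codes = np.where(dc.codes == 0, 3, np.where(dc.codes == 1, 0, dc.codes)).astype(np.uint8)
        cf = ImpactRaster(cf_codes, "autumn", "CF", dc.year, dc.grid)
        brute = int((cf.flagged & ~r["DD"].flagged).sum())
        rep = check_nesting(dc, r["DD"], cf)
        assert rep.cf_not_dd == brute and rep.total_violations > 0
        rep2, (dc2, dd2, cf2) = check_nesting(dc, r["DD"], cf, enforce=True)
        assert check_nesting(dc2, dd2, cf2).total_violations == 0

    def test_grid_mismatch_rejected(self, classified):
        r = self._rasters(classified)
        other = self._rasters(classified, year=2015)
        with pytest.raises(Exception, match="same crop, year"):
            check_nesting(r["DC"], r["DD"], other["CF"])


class TestFileConvention:
    def test_filenames(self):
        assert impact_filename("autumn", "DC", 2013) == "Autumn_DC_2013.tif"
        assert impact_filename("summer", "DD", 2007) == "Summer_DD_2007.tif"
        assert impact_filename("early_rice", "CF", 2020) == "ER_CF_2020.tif"

    def test_write_read_round_trip(self, classified, tmp_path):
        cube, masks, calib = classified
        raster = classify(cube, masks, calib, "autumn", "CF", 2014)
        path = write_impact_tiff(raster, tmp_path)
        assert path.name == "Autumn_CF_2014.tif"
        back = read_impact_tiff(path)
        assert np.array_equal(back.codes, raster.codes)
        assert back.grid == raster.grid
        assert (back.crop, back.degree, back.year) == ("autumn", "CF", 2014)
        # byte-stable rewrite
        data1 = path.read_bytes()
        write_impact_tiff(back, tmp_path)
        assert path.read_bytes() == data1

    def test_bad_filename_rejected(self, tmp_path):
        p = tmp_path / "Rice_DC_2013.tif"
        p.write_bytes(b"x")
        with pytest.raises(ValueError, match="convention"):
            read_impact_tiff(p)


class TestMerge:
    def _block(self, grid, rows, code):
        codes = np.full(grid.shape, INVALID_CODE, dtype=np.uint8)
        codes[rows, :] = code
        return ImpactRaster(codes, "autumn", "DC", 2010, grid)

    def test_disjoint_union_and_identity(self):
        grid = dl.GridSpec(6, 4)
        a = self._block(grid, slice(0, 3), 1)
        b = self._block(grid, slice(3, 6), 0)
        merged = merge_regions([a, b])
        assert (merged.codes[:3] == 1).all() and (merged.codes[3:] == 0).all()
        empty = ImpactRaster(np.full(grid.shape, INVALID_CODE, np.uint8), "autumn", "DC", 2010, grid)
        again = merge_regions([merged, empty])
        assert np.array_equal(again.codes, merged.codes)

    def test_totals_are_additive(self):
        grid = dl.GridSpec(6, 4)
        a = self._block(grid, slice(0, 2), 1)
        b = self._block(grid, slice(4, 6), 1)
        merged = merge_regions([a, b])
        assert merged.area_thousand_ha() == pytest.approx(
            a.area_thousand_ha() + b.area_thousand_ha()
        )

    def test_conflicting_overlap_rejected(self):
        grid = dl.GridSpec(6, 4)
        a = self._block(grid, slice(0, 3), 1)
        b = self._block(grid, slice(2, 4), 0)
        with pytest.raises(ValueError, match="conflicting"):
            merge_regions([a, b])


def test_area_summary_matches_raster_counts(classified):
    cube, masks, calib = classified
    rasters = [classify(cube, masks, calib, "autumn", "DC", y) for y in (2011, 2014)]
    table = area_summary(rasters, masks)
    for r in rasters:
        sub = table[(table["year"] == r.year) & (table["region_id"] == "south")]
        assert sub["area_thousand_ha"].sum() == pytest.approx(
            (r.flagged & masks.region_mask("south")).sum() * 0.025
        )
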