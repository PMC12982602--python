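"""Generator contracts: determinism, event arithmetic, statistics oracle."""

import numpy as np
import pytest

import droughtlai as dl
from droughtlai.synthetic import DroughtEvent, RegionSpec
from conftest import small_config, small_region


def brute_force_stats(cube, masks, truth):
    """Independent per-pixel oracle for noise-free statistics.

    Loops over pixels and composites with plain indexing; 25 ha per 500 m
    pixel, i.e. 0.025 thousand ha.
    """
    out = {}
    for region in truth.baseline_years:
        base_year = truth.baseline_years[region]
        bi = cube.years.index(base_year)
        for year in cube.years:
            yi = cube.years.index(year)
            for degree in ("DC", "DD", "CF"):
                count = 0
                for crop in truth.seasons[region]:
                    w = truth.windows[(region, crop)]
                    sl = slice(w.start_index, w.end_index + 1)
                    t = truth.thresholds[(region, crop, degree)]
                    mask = masks.crop_in_region(crop, region)
                    for r, c in zip(*np.where(mask)):
                        base = np.mean(cube.values[bi, sl, r, c])
                        if base <= 0:
                            continue
                        actual = np.mean(cube.values[yi, sl, r, c])
                        if actual <= (t / 100.0) * base:
                            count += 1
                out[(region, year, degree)] = count * 0.025
    return out


def test_seeded_determinism():
    a = dl.generate_lai_cube(small_config(seed=7))
    b = dl.generate_lai_cube(small_config(seed=7))
    assert np.array_equal(a[0].values, b[0].values)
    assert np.array_equal(a[1].region_ids, b[1].region_ids)
    c = dl.generate_lai_cube(small_config(seed=8))
    assert not np.array_equal(a[0].values, c[0].values)


def test_no_events_no_noise_every_year_matches_baseline():
    cube, masks, truth = dl.generate_lai_cube(small_config(noise_sd=0.0))
    base = cube.values[cube.years.index(2006)]
    for year in cube.years:
        assert np.array_equal(cube.values[cube.years.index(year)], base)


def test_event_depresses_exact_pixel_count():
    """fraction 0.25 on a 100-pixel region, depression 0.5: exactly 25 pixels
    at half their baseline window-mean."""
    region = small_region(events=[DroughtEvent(2008, "autumn", 0.25, 0.5)])
    cube, masks, truth = dl.generate_lai_cube(small_config(regions=[region]))
    w = truth.windows[("r1", "autumn")]
    sl = slice(w.start_index, w.end_index + 1)
    base = cube.values[cube.years.index(2006), sl].mean(axis=0)
    actual = cube.values[cube.years.index(2008), sl].mean(axis=0)
    halved = np.isclose(actual, 0.5 * base)
    assert halved.sum() == 25
    assert np.array_equal(actual[~halved], base[~halved])


def test_noise_free_stats_match_brute_force_oracle():
    region = small_region(
        events=[
            DroughtEvent(2008, "autumn", 0.3, 0.5),  # ratio 0.5: inside DD
            DroughtEvent(2010, "autumn", 0.5, 0.75),  # ratio 0.25: inside CF
        ]
    )
    cube, masks, truth = dl.generate_lai_cube(small_config(regions=[region]))
    stats = dl.derive_historical_stats(cube, masks, truth, 0.0)
    oracle = brute_force_stats(cube, masks, truth)
    for (r, y, d), area in oracle.items():
        assert stats.value(r, y, d) == pytest.approx(area, abs=1e-12)


def test_forty_flagged_pixels_is_one_thousand_ha():
    region = small_region(events=[DroughtEvent(2008, "autumn", 0.4, 0.9)], shape=(10, 10))
    cube, masks, truth = dl.generate_lai_cube(small_config(regions=[region]))
    stats = dl.derive_historical_stats(cube, masks, truth, 0.0)
    # depression 0.9 -> ratio 0.1, flagged at every degree; 40 pixels
    for degree in ("DC", "DD", "CF"):
        assert stats.value("r1", 2008, degree) == pytest.approx(1.0)


def test_stats_severity_nesting(two_region_run):
    _, _, _, _, stats = two_region_run
    for region in stats.regions:
        dc = stats.series(region, "DC")
        dd = stats.series(region, "DD")
        cf = stats.series(region, "CF")
        assert (cf <= dd + 1e-12).all() and (dd <= dc + 1e-12).all()


def test_baseline_year_is_series_minimum(two_region_run):
    _, _, _, truth, stats = two_region_run
    for region, base_year in truth.baseline_years.items():
        for degree in ("DC", "DD", "CF"):
            s = stats.series(region, degree)
            assert s.loc[base_year] == pytest.approx(s.min())


@pytest.mark.parametrize("depressions", [(0.2, 0.5), (0.5, 0.8)])
def test_deeper_depression_never_shrinks_area(depressions):
    areas = []
    for d in depressions:
        region = small_region(events=[DroughtEvent(2008, "autumn", 0.4, d)])
        cube, masks, truth = dl.generate_lai_cube(small_config(regions=[region]))
        stats = dl.derive_historical_stats(cube, masks, truth, 0.0)
        areas.append(
            sum(stats.value("r1", 2008, deg) for deg in ("DC", "DD", "CF"))
        )
    assert areas[1] >= areas[0]


def test_stats_noise_is_multiplicative_and_seeded():
    region = small_region(events=[DroughtEvent(2008, "autumn", 0.4, 0.5)])
    cube, masks, truth = dl.generate_lai_cube(small_config(regions=[region]))
    clean = dl.derive_historical_stats(cube, masks, truth, 0.0)
    noisy1 = dl.derive_historical_stats(cube, masks, truth, 0.1)
    noisy2 = dl.derive_historical_stats(cube, masks, truth, 0.1)
    assert noisy1.frame.equals(noisy2.frame)  # rng derived from truth seed
    nz = clean.frame["area_thousand_ha"] > 0
    assert not np.allclose(
        noisy1.frame.loc[nz, "area_thousand_ha"], clean.frame.loc[nz, "area_thousand_ha"]
    )
    # zeros stay zero under multiplicative noise
    assert (noisy1.frame.loc[~nz, "area_thousand_ha"] == 0).all()


def test_generator_input_validation():
    with pytest.raises(ValueError, match="non-negative"):
        dl.derive_historical_stats(*dl.generate_lai_cube(small_config()), -0.1)
    with pytest.raises(ValueError, match="event year"):
        small_config(regions=[small_region(events=[DroughtEvent(1999, "autumn", 0.1, 0.1)])]).validate()
    with pytest.raises(ValueError, match="not grown"):
        small_config(regions=[small_region(events=[DroughtEvent(2008, "summer", 0.1, 0.1)])]).validate()
    with pytest.raises(ValueError, match="baseline year"):
        small_config(regions=[small_region(events=[DroughtEvent(2006, "autumn", 0.1, 0.1)])]).validate()
    with pytest.raises(ValueError, match="decrease with severity"):
        small_config(regions=[small_region(thresholds=(40, 60, 80))]).validate()
    # overlapping rectangular regions on one pixel
    r1 = small_region()
    r2 = small_region()
    r2.region_id = "r2"
    with pytest.raises(ValueError, match="overlap"):
        dl.generate_lai_cube(small_config(regions=[r1, r2]))


def test_fill_missing_year_masks_copies_previous():
    from droughtlai.synthetic import fill_missing_year_masks

    m2018 = np.zeros((3, 3), dtype=bool)
    m2018[0, 0] = True
    m2019 = np.ones((3, 3), dtype=bool)
    out = fill_missing_year_masks({2018: m2018, 2019: m2019}, [2018, 2019, 2020])
    assert np.array_equal(out[2020], m2019)
    assert np.array_equal(out[2018], m2018)
    with pytest.raises(ValueError, match="no mask"):
        fill_missing_year_masks({2019: m2019}, [2018, 2019])
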