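import numpy as np
import pytest

import droughtlai as dl
from droughtlai.synthetic import DroughtEvent, RegionSpec, SimulationConfig


def small_region(
    *,
    crops=("autumn",),
    thresholds=(80, 60, 40),
    events=(),
    shape=(10, 10),
    baseline_year=2006,
    crop_cover=1.0,
):
    tdc, tdd, tcf = thresholds
    return RegionSpec(
        region_id="r1",
        row_slice=(0, shape[0]),
        col_slice=(0, shape[1]),
        crops=tuple(crops),
        growing_season={c: (145, 273) for c in crops},
        truth_thresholds={
            (c, d): t for c in crops for d, t in zip(("DC", "DD", "CF"), (tdc, tdd, tcf))
        },
        truth_windows={c: (185, 225) for c in crops},
        baseline_year=baseline_year,
        drought_events=list(events),
        crop_cover=crop_cover,
    )


def small_config(seed=0, *, years=range(2006, 2012), noise_sd=0.0, regions=None, shape=(10, 10), **kw):
    return SimulationConfig(
        seed=seed,
        grid_shape=shape,
        years=list(years),
        regions=regions if regions is not None else [small_region(shape=shape)],
        noise_sd=noise_sd,
        **kw,
    )


@pytest.fixture(scope="session")
def two_region_run():
    """Noise-free two-region scenario, generated once: (cfg, cube, masks, truth, stats)."""
    cfg = dl.two_region_scenario(seed=11)
    cube, masks, truth = dl.generate_lai_cube(cfg)
    stats = dl.derive_historical_stats(cube, masks, truth, 0.0)
    return cfg, cube, masks, truth, stats


@pytest.fixture(scope="session")
def two_region_calibration(two_region_run):
    cfg, cube, masks, truth, stats = two_region_run
    calib = dl.calibrate_all(cube, masks, stats, truth.seasons)
    return calib


@pytest.fixture
def rng():
    return np.random.default_rng(42)
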