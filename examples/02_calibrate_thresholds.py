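"""Recover relative LAI thresholds and key windows from annual statistics.

Runs the grid search (all candidate windows x thresholds 0..100%) per
region and severity degree against the simulated statistics and compares
the recovered parameters with the generator's ground truth.
"""

import droughtlai as dl
from droughtlai.report import recovery_summary

cfg = dl.two_region_scenario(seed=7)
cube, masks, truth = dl.generate_lai_cube(cfg)
stats = dl.derive_historical_stats(cube, masks, truth, stats_noise_cv=0.0)

calib = dl.calibrate_all(cube, masks, stats, truth.seasons)

print(calib.table().to_string(index=False))
# t_percent is the recovered relative threshold (percent of the baseline
# year's window-mean LAI); the window DOYs are the selected key
# phenological period; r/rmse score the estimated-vs-historical annual
# series for that region and degree.

rec = recovery_summary(truth, calib)
print("\nrecovery vs ground truth:")
print(rec.to_string(index=False))
# With noise-free statistics the recovered thresholds equal the truth and
# the estimated series reproduces the statistics exactly (R=1, RMSE=0).
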