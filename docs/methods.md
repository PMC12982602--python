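# Methods

## Model and procedure

`droughtlai` implements a relative-threshold impact model on gridded LAI.
The object of inference, per (region, crop-season class, severity degree),
is a pair (T, W): an integer percentage threshold T and a time window W
drawn from the contiguous runs of 8-day composites inside the crop's
growing season. Pixel *i* is impacted in year *y* when its window-mean LAI
satisfies `LAI_i(y) <= (T/100) * LAI_i(base)`, where `base` is the baseline
year. Using a *relative* threshold absorbs spatial heterogeneity in
absolute LAI (soil, topography, cultivar): a pixel is compared only against
its own baseline state, never against other pixels.

Extraction converts the flagged-pixel count to area at 25 ha per 500 m
pixel (0.025 thousand ha). Per region and degree, the estimated annual
series is the sum of per-crop extracted areas plus the baseline year's
historical area (HA_base), which accounts for the residual impact present
even in the calmest year. Agreement with the historical series is measured
by the Pearson correlation R (temporal consistency) and the RMSE in
thousand ha (magnitude error).

### Baseline year

The baseline is the year minimising the sum of the three degree areas in
the historical statistics (ties break to the earliest year). It can be
overridden per region in the pipeline configuration, e.g. to reproduce a
fixed published choice. For any T < 100 the extraction of the baseline year
against itself is identically zero, so the estimated series equals HA_base
there — a structural identity the tests assert.

### Search and selection

The search is exhaustive over the candidate grid: every window (m(m+1)/2
candidates for m composites in season; 153 for the 17-composite DOY
145–273 season) times every integer threshold 0..100 (inclusive, 101
values). "Highest R and lowest RMSE" is resolved lexicographically:
maximise R; break ties by minimal RMSE, then by smaller T, then by earlier
window start, then by shorter window. R and RMSE are quantised at 1e-9 for
the ordering only, so candidates whose series are equal up to
floating-point noise fall through to the deterministic tie-breaks; reported
metrics are unrounded. Candidates whose estimated series has zero variance
(R undefined) are never selected; a constant historical series raises an
error, since no candidate can be scored against it.

Regions with several crop classes are calibrated by coordinate descent:
all crops start at T = 100 with the full-season window, then crops are
swept in a fixed order (summer, autumn, early rice), each sweep exhaustive
in that crop's (window, T) with the others held fixed, until a full sweep
changes nothing (at most 10 sweeps). This reduces to the exhaustive search
for single-crop regions and is deterministic, but it is a local method: a
degree constrained by few event years can converge to a near-optimal
non-truth solution (observed on the double-cropping test scenario for the
crop-failure degree). Per-degree calibrations are independent; threshold
ordering across degrees is checked and reported, not enforced during
calibration.

### Mapping

Classification applies each region's calibrated (T, W) per pixel and writes
one GeoTIFF per (crop, degree, year) named `{Crop}_{Degree}_{Year}.tif`
(Summer / Autumn / ER; DC / DD / CF). Each file carries only its own
degree's code plus 0 (assessed, no impact) and 99 (invalid/non-crop, also
the nodata value): one file per degree is the only reading consistent with
the filename schema, and 0 distinguishes "assessed and unimpacted" from
"not assessable". Pixels with a zero or invalid baseline window-mean are
coded 99 — with a zero baseline the indicator would flag bare ground as
drought. With ordered thresholds (T_CF <= T_DD <= T_DC), the per-degree
flag sets nest (CF ⊆ DD ⊆ DC); an optional enforcement mode promotes
milder flags where nesting is violated.

## Pre-processing

* **Smoothing.** Savitzky–Golay per pixel per year over the 46-composite
  series, never across year boundaries. The configured defaults (window 3,
  polynomial order 3) are degenerate — a cubic through three points is
  underdetermined — so the order is clamped to window − 1 with a warning.
  Note that the clamped configuration (order = window − 1) is the
  *interpolating* filter, i.e. exactly the identity; the package returns it
  as such rather than through numerically solved coefficients. Genuine
  smoothing requires a larger window (e.g. 5 or 7 with order 2). Edge
  handling fits a single polynomial to the first/last window and evaluates
  it at the off-centre positions, which preserves series length and exact
  reproduction of polynomials up to the filter order; mirror padding was
  rejected because it breaks polynomial reproduction at the edges.
* **Fill handling.** Sentinel codes only mark entries invalid; valid values
  are never altered. Window means average the valid composites inside the
  window; a pixel with no valid composite in the window is excluded from
  extraction and coded 99 downstream. Before smoothing, gaps are linearly
  interpolated so the fit is unbiased, but interpolated positions stay
  invalid.
* **Alignment.** Nearest-neighbour only, within one CRS (each target pixel
  takes the source pixel containing its centre); categorical rasters are
  never interpolated. Cross-CRS reprojection is out of scope.

## Synthetic study scenarios

The generator emulates the study design end to end so each stage is
testable by parameter recovery:

* **Phenology**: per crop season a raised-cosine bell over the growing
  season, zero at the season edges, scaled by a per-pixel amplitude drawn
  once (uniform 2–6, typical peak crop LAI) and reused every year — so
  with no events and no noise each year repeats the baseline exactly.
  A small additive background (default 0.1 LAI) represents non-canopy
  signal. Double cropping is supported: a pixel may carry both the summer
  and autumn masks, and its curve is the sum of both bells.
* **Regions** are rectangular blocks (trivially verifiable, no geometry
  dependency); each declares crops, growing seasons, truth thresholds
  (decreasing with severity), truth windows, a baseline year, and drought
  events.
* **Drought events** multiply the affected pixels' LAI inside the crop's
  truth window by (1 − depression) for one year; the affected pixel count
  is round(fraction × crop pixels). The baseline year admits no events.
* **Statistics** are the extraction of the generated cube under the truth
  parameters (the same indicator rule the search uses), times a
  multiplicative lognormal factor with unit mean and configurable CV —
  areas are positive and survey errors plausibly proportional. With CV = 0
  the statistics are exactly recomputable by an independent per-pixel loop.

Default scenario conditions follow the study design the method targets:
15 years (2006–2020), 46 composites per year at 500 m, an event-free
baseline year, three to four drought events per region with severities
placed at the truth-threshold boundaries so that every degree is
represented in the statistics, and 5% statistics noise in the noisy
recovery experiment. Problem sizes (grids of 12×12 to 40×30 pixels per
scenario) are chosen so the full calibration remains a sub-second to
few-second computation while leaving hundreds of pixels per region.

### What the generator does and does not emulate

It reproduces the *structure* real data present to the method — relative
LAI depressions, spatial amplitude heterogeneity, severity-ordered
statistics, an imperfect baseline. It does not model weather or soil
moisture, spectral bands, cloud/gap artifacts beyond sentinel masking, or
the empirical distribution of MODIS LAI heterogeneity; passing recovery
tests therefore demonstrates correctness of the estimation machinery, not
expected accuracy on real MODIS/bulletin data.

### Identifiability and the noisy-recovery design

Two properties of the synthetic world matter for interpreting recovery
results. First, because an event depresses the whole truth window
uniformly, any sub-window of the truth window yields the same relative
depression: the window is identified only up to subsets of the truth
window, and the identified quantity is the estimated-area series (the
selection tie-breaks make the choice deterministic). Second, the additive
background makes the actual/baseline ratio under *partially* overlapping
windows vary continuously across pixels (the background does not scale
with amplitude). The candidate family then contains a near-continuum of
estimated series, and maximising R over ~15,000 candidates against 15
noisy observations can overfit: a degree constrained by a single event
year recovers the threshold reproducing the *noisy* statistic rather than
the truth. The replicated noisy-recovery scenario therefore uses a
canopy-only signal (background 0), under which the candidate family is
discrete and the truth threshold is recovered; the general-purpose
scenarios keep the background. The same trade-off applies to real data:
sparse, noisy statistics bound how precisely the threshold is identified.

## Numerical choices

* Window means inside the calibration tables use the same reduction order
  and the same inclusive comparison (`actual <= (T/100)*baseline`) as the
  public extraction operation, so grid-search areas agree bit-for-bit with
  a direct extraction — asserted by an oracle-equivalence test.
* The per-pixel minimal flagging threshold is seeded from ceil(100·ratio)
  and then corrected by exact comparisons, so boundary pixels (ratio at a
  threshold) classify identically everywhere.
* Thresholds are integers; areas are exact multiples of 0.025 thousand ha;
  impact codes are an integer band with nodata 99 for bit-exact round
  trips.
* Randomness: every generator draw flows from one `numpy` `SeedSequence`;
  the statistics-noise RNG is derived from the scenario seed so
  `derive_historical_stats` is deterministic given its inputs.

## File formats

The LAI cube is stored as a single classic-format NetCDF stack (year ×
composite × y × x, with the affine/CRS parameters as global attributes);
masks, region labels and impact maps are single-band GeoTIFFs written with
explicit GeoTIFF tags (pixel scale, tiepoint, EPSG geokey, GDAL nodata).
Statistics, calibration results, estimated-vs-historical series,
validation tables and recovery summaries are tidy CSVs. Every pipeline
artifact carries a `.provenance.json` sidecar (config hash, seed,
versions); artifacts from a different configuration are never silently
overwritten.

## Known limitations

* The coordinate-descent multi-crop search is a documented approximation;
  exhaustive joint search over three crops would cost (windows × 101)³.
* The severity-degree files' per-degree coding means a year's three maps
  must be read together to reconstruct the full severity field.
* Pearson R is undefined for constant series; regions whose statistics
  never vary cannot be calibrated (raised as an explicit error).
* Thresholds are calibrated at regional scale and applied uniformly within
  a region; sub-regional variation in crop mixtures is not modelled.
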