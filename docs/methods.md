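# Methods

## Problem and model

`cropdep` builds national-scale annual inputs of atmospheric nitrogen
deposition to cropland, 1961–2020, from three kinds of gridded inputs: N
deposition maps that exist only for scattered "anchor" years, annual N
emission maps (1970–2018), and cropland maps at finer resolution than the
deposition grid. The national value for a country–year is the
cropland-area-weighted mean of cell deposition rates,

    rate_c = Σ_i dep_i · w_i / Σ_i w_i ,   w_i = cropland_i · share_ic ,

with `share_ic` the fraction of cell *i* inside country *c*, and the national
total `rate_c × cropland_c × 1e-9` in Tg N yr⁻¹. Countries with zero
cropland weight in a year are reported as NaN, matching the published table
convention.

## Grid geometry and regridding

Grids are regular lat/lon. Cell areas are true spherical quadrilateral
areas, `A = R²·Δλ·(sin φ_top − sin φ_bot)` with R = 6371 km, expressed in
hectares — "resolution × fraction" bookkeeping in degrees would make the
hectare and teragram units meaningless. Cropland maps are brought to the
deposition grid by conservative summation: each fine cell's area is
apportioned to coarse cells by fractional spherical overlap (exact for
nested integer-ratio grids, overlap-weighted otherwise), which conserves the
global total to rounding error. Only extensive quantities (areas, masses)
may be regridded this way; the API rejects rates and fractions.

Longitudes are normalized to [−180, 180) and overlap computation tries ±360°
shifts, so dateline-crossing grids work. Latitude axes are stored ascending.

Country masks are fractional: a cell's share in a country is the polygon/cell
overlap area in degree coordinates over the cell's degree area (consistent
with a point-in-polygon Monte Carlo sampled uniformly in degrees; the
spherical weighting enters through the cropland-area weights, not the
share). Pre-rasterized integer code grids give 0/1 shares. A
majority-assignment mode (whole cell to the largest claimant) exists for
comparison; fractional splitting is the default because country borders cut
coarse cells at 0.5°–2.5° resolutions.

## Cropland year rules

Decadal-style (HYDE-like) sources: 1961–1965→1960, 1966–1975→1970,
1976–1985→1980, 1986–1995→1990, 1996–2000→2000, 2001–2017→annual,
2018–2020→2017. Annual-until-2015 (LUH2-like) sources: identity up to 2015,
then the 2015 map is held. LUH2-like inputs arrive as five crop-functional-
type fractions (C3 annual, C3 perennial, C4 annual, C4 perennial, C3
N-fixing); the cell's cropland fraction is the **maximum** of the five.
That rule likely undercounts mixed-crop cells, so a `sum` mode is available
behind a flag, but `max` is the default for fidelity to the published
procedure. The max is taken at native resolution, then areas are regridded;
the alternative order (regrid fractions first) is not offered because the
max does not commute with averaging.

## Gap-filling

All fills are per grid cell, with no spatial pooling:

* **1961–1969** — the line through the 1960 and 1970 anchor maps evaluated
  at the year (`dep = β0 + β1·year`).
* **1971–1996 non-anchor years** — ordinary least squares of deposition on
  total (NOx + NH₃) emission over the early anchors {1970, 1980, 1990,
  1997}, evaluated at each year's emission map (`dep = β0 + β1·emission`,
  raw fluxes, not log).
* **2014–2018** — the same regression refit on the late anchors 1997–2013.
* **2019–2020** — emission data end in 2018; the 2018 field is held.

Anchor years pass through bit-identically. Negative predictions are clipped
at 0 (deposition is a non-negative flux); clip counts are logged per year.
Cells with zero emission variance across anchors fall back to the mean
anchor deposition with zero slope — continuity without inventing a trend.
A bivariate (per-species) regression is available behind a flag but off by
default, since the combination rule for the two species is a single summed
covariate. When deposition input is already annual, gap-filling is bypassed;
regime selection is driven by the declared anchor-availability pattern, not
by dataset names.

## Station validation arithmetic

Daily wet-deposition flux from precipitation chemistry is
`conc (mg L⁻¹) × precip (mm) × 0.01` kg N ha⁻¹ day⁻¹ (1 mm on 1 ha is 10⁴ L,
so 1 mg L⁻¹ deposits 10 g ha⁻¹). The annual flux is `365 × mean` of the
available daily fluxes; 365 is used for every year including leap years.
Products are compared country-level value versus the distribution of station
annual fluxes in that country (median, quartiles by linear interpolation
between order statistics, and min–max range), not via nearest-cell
extraction; station precipitation is taken from the station record itself
rather than paired from a gridded product.

## NUE sensitivity

`NUE = N_CR / (N_SF + N_MN + N_BNF + N_AD)` per country–year, NaN when the
denominator is zero and deliberately not capped at 1 (soil N mining can push
removal above inputs). Sensitivity across deposition products is reported
as the elementwise NUE difference against the reference product and the
per-country Pearson correlation of the NUE series over years (Spearman
behind a flag). NaN years are pairwise-deleted; fewer than 3 paired years
gives NaN with a warning.

## Synthetic world

The generator emulates the input structure with known ground truth. Per
cell, deposition is `base + trend·(year − 1990)` up to 2018 and held for
2019–2020 (mirroring the pipeline's hold rule); `base` is a smooth low-order
harmonic field around 12 kg N ha⁻¹ yr⁻¹ with per-cell trends of s.d.
0.08 kg N ha⁻¹ yr⁻², kept positive over the whole period by construction —
magnitudes of the order seen in national deposition series. Emission is
exactly `(dep − a)/b` per cell, so deposition is exactly affine in emission
and exactly linear in year: a noise-free world is recoverable by the
gap-filling regressions to rounding error, which is the end-to-end test.
`sigma` adds Gaussian noise to the *observed anchor deposition maps* (the
regressand), leaving truth and emissions clean, so OLS slope estimates stay
unbiased and their sampling spread is testable. Cropland is five fraction
fields on an integer-ratio finer grid; countries are contiguous lat/lon
blocks with exact 0/1 shares (a polygon mode exercises the rasterizer).
Station records are constructed so each station's annualized flux equals a
chosen target — three stations per country bracketing the national truth
rate at 0.8×/1×/1.2× — and budget tables are built backwards from a drawn
target NUE. The ground-truth national table is computed at generation time
by an independent direct per-cell loop, not by the aggregation code under
test. All randomness flows from one seed through named spawned substreams.

What the generator does **not** emulate: the spatial covariance of real
chemistry-transport model output, interannual emission variability
decoupled from deposition, dry/wet partitioning, and reporting gaps in real
station networks. Passing tests therefore demonstrate correctness of the
arithmetic and plumbing under the stated availability patterns, not the
realism of any particular deposition product.

## Numerical choices

* Overlap weights below 1e-12 are treated as no coverage; per-cell country
  shares may sum to at most 1 + 1e-9 before an error is raised.
* Missing fine cells contribute zero to a regridded sum unless every
  contributing cell is missing, in which case the coarse cell is missing.
* Grid spacing must be uniform to 1e-9°; grid equality is exact on cell
  centers.
* OLS is computed from centered sums per cell; the suite checks equality
  with the normal-equations solution to 1e-10.
* Problem sizes in the tests and the acceptance script (20×40 deposition
  grid with a 4× finer cropland grid and 8 countries for end-to-end runs;
  3×4 grids with 200 replicates for the noise study) were chosen so the
  whole suite completes in well under a minute while keeping every regime
  of the pipeline exercised.

## Known limitations

* GeoTIFF mask input is not supported; masks arrive as NetCDF integer code
  grids or GeoJSON polygons. NetCDF files are written in classic format.
* Polygon rasterization is exact but loops over cells; it is meant for
  country-scale polygons on coarse grids, not for 5′ global masks (use a
  pre-rasterized code grid there).
* The station comparison assumes the generic CSV layout; network-specific
  formats must be converted upstream.
* No uncertainty propagation on the regression coefficients; the pipeline
  reports point estimates only.
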