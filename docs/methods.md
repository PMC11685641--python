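# Methods

This note documents the models, conventions, and numerical choices behind
the package, and what its synthetic-data tests do and do not demonstrate.

## The common grid

All layers share one regular longitude–latitude grid, 9° × 3° by default,
from the pole to 45°S (40 × 15 cells). Bins are half-open `[lo, hi)` on
both axes with the longitude origin at −180° and +180° wrapping onto the
−180° column; this guarantees that every in-range coordinate belongs to
exactly one cell. The exact northern limit of the mapped domain is not
sharply defined in practice (data products variously start at 45–50°S), so
it is a configuration parameter.

Cell areas use the spherical-zone formula A = R² Δλ (sin φ_hi − sin φ_lo)
on an authalic sphere, R = 6371.0072 km. Density-type quantities are
reported per 10,000 km². The grid deliberately extends to the pole even
though high-latitude cells are largely land or permanent ice: land/ocean
masking is a property of each data layer (cells simply have no data), not
of the grid.

## Zero-assimilating geometric mean

Krill net catches and chlorophyll concentrations are right-skewed, so cells
are summarised by geometric rather than arithmetic means. Zeros are
assimilated following Habib's extension of the geometric mean: for n
observations with n₊ positive,

    G = (n₊ / n) · exp( mean of ln x over the positive x ),

the nonnegative-data special case of the signed estimator. G equals the
ordinary geometric mean when all values are positive, 0 when all are zero,
and is never larger than the geometric mean of the positive subset. The
formula lives in a single function (`geometric_mean_with_zeros`) so an
alternative zero treatment can be swapped in, and the test suite checks it
against an independently written product-form implementation.

Point samples are month-filtered (January–March by default, matching when
most krill sampling happens) before pooling; all years are pooled within a
cell in a single geometric mean. Fine rasters are aggregated by the same
estimator over the fine cells whose centres fall in each coarse cell —
centre-in-cell membership, not areal weighting, which at 1/12° versus 9°×3°
differs negligibly and keeps the operation exact to test.

## Five-step trend estimation

Per cell: (1) daily series are reduced to calendar-month means (inputs
already monthly skip this); (2) a per-calendar-month climatology is
averaged over a reference window, 1993–2014 by default; (3) subtracting it
gives anomalies; (4) anomalies are decomposed additively in the classical
X11 style — initial trend by a centred 2×12 moving average, detrending,
initial seasonal by a 3×3 moving average within each calendar month
re-centred by a 2×12 moving average, deseasonalising, refined trend by the
13-term Henderson filter, refined seasonal by a within-month 3×5 average
re-centred the same way, irregular as the remainder (so the three
components reconstruct the input exactly by construction); (5) the gradient
is the OLS slope of the trend component against time, with a two-sided
t-interval (95%) and t-test; p > 0.05 marks a cell insignificant.

Numerical choices that matter:

* **Endpoint weights.** Truncated filter windows at the series ends are
  renormalised to preserve both level and slope (zeroth and first moments),
  which reduces to plain sum-renormalisation for symmetric windows and lets
  any linear series pass through every filter unchanged. Simple
  sum-renormalisation would distort even a noiseless ramp near the ends by
  tens of percent of the monthly increment.
* **Core-restricted fitting.** The OLS line is fitted only where every
  filter feeding the trend component is fully symmetric — 42 months in from
  each end. This makes the noiseless limit exact (injected gradients are
  recovered to ~1e−17) instead of carrying endpoint distortion into the
  slope. The refined *seasonal* component has a deeper dependency chain and
  is filter-clean only ~84 months in; tests of seasonal properties use that
  wider margin.
* **Time coordinate.** Monthly points are treated as uniformly spaced at
  nominal mid-month decimal years, `year + (month − 0.5)/12`. Data-weighted
  mean dates are non-uniform (month lengths differ), which measurably
  biases the slope of an index-linear trend component; nominal spacing is
  also the climate-community convention.
* **Gaps.** Interior gaps of at most 2 months are bridged by linear
  interpolation of the anomalies; longer interior gaps mark the cell as
  failed (recorded per cell, the map continues). Leading/trailing missing
  spans are trimmed. A decomposition needs 36 consecutive months; a trend
  fit needs 87 (core margin both sides plus three points).
* **What is fitted.** The line is fitted to the X11 trend component by
  default; fitting the seasonally adjusted series (trend + irregular) is a
  configuration switch. Because the trend component is heavily smoothed,
  its residuals are serially correlated and the nominal p-values of the
  per-cell fit are anticonservative; the significance threshold (0.05) is
  applied to those nominal values deliberately, for fidelity to the mapped
  product this mirrors. The type-I-error test therefore exercises the OLS
  t-test directly on white-noise series, where its 5% level is exact.

## Human-activity proxies

Ship-day records per vessel, cell, and year are multiplied by the typical
persons aboard for the vessel's type (fishing, tourist, cargo/supply,
research, other — values are user configuration; the synthetic defaults are
40/250/30/60/25), summed within type, and averaged across the years in the
record set (years with no traffic in a cell count as zeros). The total
layer is the sum over the five types, in person-days yr⁻¹.

Facilities house 365 p person-days yr⁻¹ when year-round and 182.5 p when
seasonal (six months at peak population p). Facility influence on the ocean
is an effective population density in people per 10,000 km²: a cell
containing a facility receives p divided by the cell area; every other cell
receives p/(π d²), the population spread uniformly over the disc whose
radius is the great-circle distance d from facility to cell centroid — an
inverse-square decay. Contributions sum over facilities, making the layer
exactly additive over facility sets. A stricter disc-ratio reading
(multiplying the disc density by cell-area/disc-area, an inverse-fourth
decay) is implemented behind `remote_decay="disc_ratio"`; the inverse-square
form is the default because it is the behaviour the method is described to
have. Whether seasonal facilities should be down-weighted (p/2) in the
density proxy is genuinely open; the default uses peak population directly,
with `seasonal_weighting=True` as the alternative.

## Discrete 1–5 ranking

Each continuous layer is transformed toward normality — log for krill,
chlorophyll, ship person-days, and population density; square root for
positive SST gradients; magnitude for pH declines — and four thresholds are
placed at the interior points of a five-way equipartition of the retained
range, so each rank spans an equal transformed interval (placing thresholds
*at* the endpoints would make ranks 1 and 5 measure-zero). "Retained" means
after omitting zeros and outliers; the outlier rule is the [1st, 99th]
percentile of the transformed nonzero values, configurable, since the
original convention is only shown graphically. Zeros rank 1; values outside
the outlier bounds clip to rank 1 or 5; ties at a threshold take the higher
rank (half-open bins, consistent with the grid convention).

Trend layers rank the magnitude of *concerning* change only: for warming,
cells with significant positive gradients are ranked on the √ scale and
everything else (negative or insignificant) is rank 1; for acidification,
significant negative gradients are ranked by magnitude on an identity
scale, and positive or insignificant cells are rank 1. If the eligible set
is a single value it ranks 5 (it is the observed maximum).

## Map composition

Composite scores are plain means of the contributing layers' values,
cell-wise, using whichever contributors are present — a cell with no krill
data is defined entirely by chlorophyll, and the same available-mean rule
is applied uniformly. Maps: A = mean(krill, chl); C = mean(SST, pH);
E = mean(ships, facilities), restricted to cells entirely south of 60°S
because ship data end there; B = mean(E, A); D = mean(E, C); F = mean(B, D).
The 60°S mask propagates to B, D, and F; A and C keep their full extent.
On fully populated cells the nesting gives F = E/2 + A/4 + C/4 exactly.
Scores stay continuous (means of integer ranks are not re-discretised).

## Synthetic data: what it emulates, and what it does not

The generator produces every input the pipeline reads, with known truth:

* **Facilities** — log-normal peak populations (median 20, σ_log 1.2,
  rounded to integers), ~43% clustered inside one cell on the Peninsula
  side of the grid, the rest spread along a coastal band; 60% seasonal.
* **Ship traffic** — expected ship-days decay exponentially (~500 km
  e-folding) from facilities in proportion to their population, over a
  uniform background; Poisson counts per cell, type, and year with a
  fishing/tourist-dominated type mixture.
* **Krill samples** — a smooth coastal truth field (peaking near 66°S) with
  the hotspot cell boosted ×12; samples are zero-inflated (30%) log-normal
  (σ_log 0.75) around the cell truth, scaled so the zero-assimilating
  geometric mean estimates the truth; dates uniform over January–March.
* **Chlorophyll** — a 1/12° raster with a smooth nearshore–offshore
  gradient, a ×3 hotspot boost, and multiplicative log-normal noise.
* **Environmental series** — value = base + gradient·(t − start) + seasonal
  cycle (resolved at calendar-month level) + AR(1) noise (φ = 0.5). The
  SST-like field is daily, 1982–2021, on a 365-day no-leap calendar
  (standard in climate simulation; a leap calendar would jitter month-mean
  timestamps and break the exact noiseless limit), innovation σ = 0.5 °C;
  the pH-like field is monthly, 1985–2021, σ = 0.005. When the SST field is
  generated monthly as a reduced-size stand-in, its σ defaults to 0.18, the
  standard deviation of a monthly mean of the daily AR(1) noise, so both
  frequencies represent the same monthly noise level. The SST gradient
  truth spans ±(0.004–0.015) °C yr⁻¹ with a broad spatial pattern, a
  cooling band, and its warming maximum at the hotspot; pH truth is
  −0.0019 to −0.0025 yr⁻¹, steepest at the hotspot.

One 3×3 block of cells (centred on col 13, row 9 of the default grid) is
engineered as the joint maximum of facility population, ship traffic,
biota, and abiotic trends, so end-to-end runs have a known answer; the
planted footprint spans neighbours of the central cell because the facility
smoothing, the traffic decay scale, and the trend bump all have a spatial
extent of one to two cells.

The generator makes no attempt at ocean circulation, sea-ice dynamics,
bloom phenology, realistic sampling-effort patterns, or autocorrelated
spatial noise. Passing tests therefore demonstrate that the *pipeline*
recovers planted structure under realistic noise levels and data volumes —
not that the method would be robust to the sampling biases, spatially
correlated errors, or transport processes present in real observations.

## Problem sizes used in the test suite

Unit and property tests run on an 8×3 coarse grid or the full 40×15 grid as
appropriate. The gradient-recovery checks use the full 40-year daily field
(40 × 15 cells); the end-to-end hotspot-recovery check runs the complete
pipeline 50 times with monthly environmental series (the reduced-size
stand-in above), 112 facilities, 4000 krill samples, and the 1/12°
chlorophyll raster. The acceptance script's reference quantities are exact
formula evaluations and run in well under a second.

## Known limitations

* The X11 implementation is the classical additive core with one
  refinement pass, not the full X-11-ARIMA system (no forecasting
  extension, no moving-seasonality diagnostics); the decomposition function
  is pluggable.
* Nominal trend p-values are anticonservative when fitted to the smoothed
  trend component (see above).
* GeoJSON export writes plain cell rectangles in lon/lat; cartographic
  projection and coastline clipping are out of scope.
* The effective-population-density model is isotropic and ignores
  coastlines: a facility "influences" cells across land as readily as
  across water.
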