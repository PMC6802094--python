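# Methods

This note documents the models, rules and numerical choices implemented in
`baciveg`, the conditions its synthetic-data generator emulates, and the
limits of what its tests demonstrate.

## Study design

The package implements a before–after–control–impact (BACI) design for
protection-elevation effects on forest vegetation condition. The *impact*
units are PAs elevated to the highest protection tier (Tiger Reserves,
TRs); the *controls* are lower-tier Wildlife Sanctuaries (WLSs) that
remained unelevated. The intervention date is the TR's declaration year;
the control in a matched pair is analysed over the same epochs as its TR.
Two comparisons are made: (a) *after-only* — condition trends in the years
after declaration; (b) *before–after* — the change in trends from before
to after declaration, which controls for each pixel's historical
trajectory.

## Vegetation condition and its annual summary

Condition is measured on two complementary axes: greenness (EVI) and
canopy moisture (NDII). NDII is used rather than NDWI because the 5-band
TM-class sensor the pipeline targets lacks the 1.24 µm band NDWI needs.
EVI uses the standard coefficients G=2.5, C1=6, C2=7.5, L=1 (exposed in
`AnalysisConfig.evi_coefficients` but not varied); computed EVI outside
[−1, 2] is treated as a reflectance artifact and flagged invalid, so a
single corrupt observation cannot capture an annual minimum. Reflectances
are accepted either as [0, 1] floats or as ×10 000 scaled integers
(`reflectance_scale`).

The annual summary is the *brownest/driest composite*: the robust minimum
of the year's valid index values, i.e. the mean of the lowest
k = ⌈0.2 n_valid⌉ values (k ≥ 1, so "least 20 %" of a small count still
selects one observation). Averaging the lowest fifth instead of taking the
absolute minimum damps index noise at the cost of a small upward shift of
the dry-season level; since the shift is common to all years it does not
bias the trend. Each composite carries a fractional-year timestamp: by
default the mean timestamp of the averaged subset (consistent with
averaging the values); the timestamp of the single argmin is available via
`composite_timestamp="argmin"`. Ties at the k-th smallest value are broken
by earliest timestamp (chronological stable sort), making composites fully
deterministic. Years are calendar years; composites of minima use the
convention that peak-dry-season (pre-monsoon) conditions fall within one
calendar year.

## Trend estimation and sufficiency filters

Per-epoch trends are estimated per pixel with Sen's slope — the median of
all pairwise slopes (y_j − y_i)/(x_j − x_i) — against the composite
timestamps (not integer years), so interannual shifts in dry-season timing
enter the regression correctly. The estimator is robust to outlying years:
corrupting 1 of 10 collinear points arbitrarily leaves the slope
unchanged. "Sen's slope" is sometimes described as a repeated-medians
method; the repeated-medians estimator proper (Siegel's) is a distinct,
more breakdown-robust variant and is available via `estimator="siegel"`;
the default is the pairwise-median form. Medians of even counts are the
mean of the two central values. Pairs with identical timestamps are
excluded; a series with all-equal timestamps has no defined slope.

Sufficiency rules: a pixel needs ≥ 5 valid composite years in an epoch
(fewer than 5 drops the pixel for that epoch); a PA with strictly more
than 20 % of its pixel area insufficient in an epoch is excluded from
analyses involving that epoch. Both thresholds sit in `AnalysisConfig`.

The declaration year is assigned to the *after* epoch by default
(protection takes effect in the year it is conferred); the alternative
convention is available via `declaration_year_in_after=False`.

## Classification and comparison

Condition (after epoch): improve ⇔ both slopes > 0; decline ⇔ both < 0;
mixed signs ⇔ unclear. Condition change: the same rules on the
before-to-after slope differences, labelled helped/harmed/unclear. The
rules use strict inequalities and leave exact zeros undefined; the package
assigns zeros to *unclear* — a zero Sen slope is reachable through median
ties, and "no detectable movement on one axis" is semantically an unclear
verdict. Pixels missing any required slope are a fourth category,
*insufficient*.

PA compositions are percentages of **all** PA pixels (insufficient
included), so the ≤ 20 % insufficient share remains visible and
percentages always sum to 100. The ternary export renormalizes over the
three analysed categories only, placing each PA in the 3-simplex.

Matched-pair verdicts: *better* ⇔ the TR has strictly greater positive
share and strictly smaller negative share than its control; *worse* is the
mirror image; everything else (including exact equality on either axis) is
*ambiguous*. A pair differs *substantially* when either the positive or
the negative share differs by ≥ 15 percentage points (inclusive).

## Matching

Candidate controls for a TR: WLS status, same state (PA management in the
target system is state-level), area ≥ 75 km², |Δ mean annual rainfall| ≤
500 mm (rainfall proxies forest type; both bounds inclusive per their
"within"/"or greater" definitions). The TR takes the nearest candidate;
distance is minimum boundary-to-boundary separation by default (the most
natural reading of "shortest distance"; centroid distance is available).
When two TRs' nearest candidate is the same WLS, a deterministic order is
required: TRs are processed in ascending (declaration year, id), the
earlier-processed TR keeps the contested control, and the later one takes
its next-nearest candidate; assignments are therefore injective. TRs with
no remaining candidate are reported unmatched. PA mean rainfall can be
computed from a monthly climatology grid as the area-weighted mean over
intersecting cells of the annual total (sum of the 12 monthly means).

## Synthetic data generator

The generator emulates the structural features of a ~29-year single-sensor
record (nominally 1984–2012 at 30 m) that the pipeline must survive:

- irregular within-year observation dates (uniform spacing with jitter,
  approximating a 16-day revisit without orbital modelling);
- cloud/water gaps: independent per-observation masking with probabilities
  `cloud_fraction` / `water_fraction` recorded in a QA layer;
- additive Gaussian noise **in index space** before inversion to
  reflectances, so the injected trend is the ground truth of exactly the
  quantity the pipeline estimates;
- piecewise-linear per-pixel trends in the annual minimum of each index,
  with the slope switching at the declaration year (continuous at the
  switch), on top of a fixed seasonal cycle with its trough in the
  pre-monsoon dry season.

Reflectance inversion fixes blue (0.05) and red (0.10) and solves NIR from
the target EVI, then SWIR1 from the target NDII given that NIR — one
degree of freedom per index makes the inversion exact. Slopes that drive a
reflectance outside [0, 1] are clipped with a logged warning. The
within-year date pattern is drawn once and repeated every year; with a
fixed pattern the same observations enter the robust minimum each year, so
at zero noise the composite series is *exactly* linear with the planted
slope, and the end-to-end noiseless round trip recovers slopes to machine
precision and compositions exactly. Generated PA tables place rectangular
PAs inside disjoint per-state map blocks (areas and distances stay exact
and testable); TR areas draw from 140–2600 km², rainfall from
600–3000 mm/yr, declaration years from 1986–2000 — the size, climate and
timing ranges typical of the Indian TR network the design addresses.

What the generator does **not** emulate: radiative-transfer or phenological
realism, spatial autocorrelation of noise and clouds, topographic
illumination, sensor harmonization, land-cover conversion, or real PA
boundary shapes. Passing tests therefore demonstrate the correctness of
the estimators, rules and plumbing under known truth — not the ecological
validity of conclusions on any real landscape.

## Problem sizes and numerics

Simulated studies rasterize each PA onto its own square grid (default
32–64 px per side) covering the PA's padded bounding box; grids scale with
PA size rather than holding 30 m resolution, which keeps full simulated
studies at desk scale while exercising identical code paths. The bundled
demo analyses 9 PAs (3 TR / 6 WLS over 2 states) at 32×32 px, 12
observations/year over 1984–2012. Slope maps are computed vectorially over
all pairwise year combinations (≤ ~400 pairs/pixel); the Siegel option
falls back to a per-pixel loop and is intended for small scenes.
Determinism: every random draw descends from a single seed through named
SeedSequence streams (per-PA streams are keyed by a CRC of the PA id), so
identical configs reproduce identical outputs byte-for-byte; all
floating-point reductions use fixed-order numpy operations.

## Known limitations

- Verdicts are sign-based with no significance testing (by design: the
  classification rules are strict sign rules); a Mann–Kendall test could
  be layered on but is out of scope.
- Composition denominators include insufficient pixels; analyses whose
  convention excludes them should use the ternary export.
- `pa_mean_rainfall` loops over intersecting climatology cells; it is
  meant for coarse (tens-of-km) grids, not per-pixel climate fields.
- The boundary-distance default and the earlier-TR-keeps conflict rule are
  conventions chosen for determinism where the design admits alternatives;
  both are configurable or documented above.
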