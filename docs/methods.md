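# Methods

This note records the models implemented in `thermoscape`, the
parameter choices that matter, and what the synthetic-data tests do and
do not demonstrate.

## Trait metrics

Sprint trials record stopwatch times over six 0.25 m track segments,
two laps per trial. Velocity is segment length over segment time, and
only the individual's maximal segment velocity per test temperature
(15, 20, 25, 30, 35 °C) feeds later analysis — sprint speed is a
maximal-capacity trait, so the best segment is the least-biased
estimate. Trials flagged invalid (animal refused to move) travel in the
input files with a validity flag rather than being deleted, so
exclusions are auditable.

Thermal sensitivity is Q10 = (v2/v1)^(10/(T2−T1)), computed only over
adjacent 5 °C intervals; an individual tested only at, say, 15 and
25 °C yields no Q10 because a wider exponent averages over unlike
physiology. Population interval means are plain averages of
per-individual records.

Preference trials log cloacal temperature every 10 s for 65 min; the
first 5 min are discarded as arena acclimation. The SD uses the n−1
denominator (standard for samples of this size). The mode of a
continuous series is defined by binning at 0.1 °C — the logger's
resolution — with ties broken to the lowest bin so the statistic is
deterministic; bin indices are computed with a 1e−9 epsilon so values
lying exactly on a bin edge are classified identically across
platforms. The *population* preference range (the activity window) is
the envelope of all trials' recorded extremes, because the window is
meant to capture everything an animal voluntarily selected.

Thermal breadth is CTgape − CTmin per individual-season. CTgape
(sustained mouth-gaping) stands in for the true critical thermal
maximum throughout: it is the upper threshold the trait data actually
contain, and the performance curve's upper zero anchor defaults to the
population mean CTgape for the same reason. Both anchors are
configurable.

## Performance curve

The curve is a penalized cubic regression spline fitted to the pooled
(temperature, max velocity) points plus two zero-velocity
pseudo-observations at the anchors. Choices:

- **Basis**: 5 cubic B-spline basis functions on a clamped knot vector
  spanning [anchor_low, anchor_high] (one interior knot). Five basis
  functions match the five-temperature test design — enough for a
  peaked, asymmetric curve, too few to chase noise.
- **Penalty**: the integrated squared second derivative, assembled
  exactly by 2-point Gauss–Legendre per knot interval (second
  derivatives of cubics are piecewise linear). This is the canonical
  cubic-spline wiggliness penalty and guarantees that increasing the
  smoothing weight (default 0.1) never increases the fitted curve's
  curvature — a property the tests check. An earlier coefficient-
  difference (P-spline) penalty was rejected because that guarantee
  held only approximately on clamped knots.
- **Anchoring**: the two pseudo-observations carry weight equal to the
  number of data points, which pins the boundary close to zero without
  making the system ill-conditioned. Predictions are additionally
  clipped to ≥ 0, and the closed anchor boundary (and anything beyond
  it) predicts exactly 0, since the anchors are zero by definition.
- **Maximum**: p_max and its temperature are located on a 0.1 °C grid
  over the anchor interval — below measurement resolution, so the
  argmax is stable. Percent-of-maximum is capped at 100 to absorb
  sub-grid interpolation excess.

Exact numerical equivalence with any particular GAM implementation is
not claimed; the fit is validated against closed-form oracles (a
parabola zeroed at the anchors is inside the spline space and is
recovered to 0.01% of peak) and by ground-truth parameter recovery.

## Hourly reconstruction

Daytime (sunrise ≤ h ≤ sunset): T(h) = Tmin + (Tmax − Tmin)·
sin(π(h − sunrise)/(daylength + 4)). The +4 h stretch places the
maximum in mid-afternoon; because sunrise = 12 − daylength/2 in local
solar time, the sine peaks exactly at clock hour 14, so the
reconstructed daytime maximum reproduces Tmax exactly whenever the
daylength exceeds 4 h.

Night (after sunset): T = Ts − (Ts − Tmin_next)·ln(u)/ln(N), with Ts
the sine's sunset value, u hours since sunset (floored at 1 so the
first post-sunset hour equals Ts), and N = 24 − daylength the night
length. Pre-sunrise hours continue the previous evening's decay toward
the current day's Tmin. The series is continuous at sunset by
construction and continuous at midnight up to the slow drift of
daylength; season boundaries reuse the day's own Tmin for the missing
neighbour.

`temps[h]` is the instantaneous temperature at clock hour h (0–23,
local solar time), and "daylight hours" are integer hours with
sunrise ≤ h ≤ sunset. Counting whole clock hours matches how active
hours are tallied against the ~11 available daylight hours of a
winter day.

Sunrise/sunset use the first-order declination approximation
δ = −23.44°·cos(2π(N+10)/365.24) and cos H = −tan φ · tan δ, accurate
to a few minutes at mid-latitudes — well inside the hour-resolution of
the reconstruction. Latitudes past 66.5° are rejected rather than
mishandled. No radiative, convective or microhabitat correction is
applied: the reconstruction estimates ambient air temperature only.

A vectorized per-season implementation (`reconstruct_season_array`)
backs the landscape pipeline; a test asserts bit-level agreement with
the scalar day-by-day path.

## Exposure models

- **Cold exposure**: "below" is strict (<) — conservative, since an
  hour exactly at the threshold is not colder than it. Runs are found
  on the full concatenated series, so they may cross midnight; a
  qualifying run (≥ 6 consecutive hours, configurable) marks *every*
  calendar day it touches. Day counts are therefore monotone in the
  threshold by construction. The 6 h persistence default reflects body
  thermal inertia and filters brief dips such as passing fronts.
- **Activity window**: membership in [pref_low, pref_high] is
  inclusive, because the window ends are themselves recorded body
  temperatures. Default window 21.9–40.6 °C.
- **Daylight denominator**: `fixed-11` mode divides mean active hours
  by 11 h — the convention for table-style reporting over a mid-winter
  window, where astronomical daylength varies only between ~10.3 and
  11 h; `astronomical` mode uses the per-pixel mean daylight-hour
  count. The daylight *hour set* is always astronomical; the mode only
  pins the denominator.
- **Seasonal aggregation**: metrics are computed per season and then
  averaged across seasons with equal weight (cold-day counts per
  season; activity and performance as per-day means within season
  first). Averaging across seasons commutes with presence extraction,
  which a linearity test checks.

## Landscape pipeline

Winter windows run Dec 15 – Feb 15 inclusive (63 days; the count
follows the calendar in leap configurations), one window per starting
year, defaulting to start years 2001–2020. Grids are regular lat/lon
xarray Datasets; output rasters carry the input georeference untouched.
Presence points map to the cell with the nearest centre; points sharing
a cell collapse to one before summarizing (min/max/average per metric).
Presences on no-data cells are excluded from that metric's summary.
Normalized rasters use min-max rescaling over the grid; a spatially
constant metric has no meaningful relative scale and yields an all-NaN
normalized raster rather than an arbitrary constant.

## Synthetic data

The weather generator composes a latitudinal lapse, a seasonal
sinusoid peaking in mid-July, and an AR(1) daily anomaly shared between
a day's Tmin and Tmax — the simplest structure that preserves the
day-to-day autocorrelation the consecutive-hour cold statistic depends
on. Defaults emulate a Florida-like winter peninsula (southern-edge
annual mean 25 °C, winter-steep lapse 1.7 °C per degree latitude,
seasonal amplitude 5 °C, diurnal range 10 ± 3 °C floored at 0.5 °C,
AR(1) coefficient 0.7 with stationary SD 3 °C), spanning roughly
Tmin 15/Tmax 25 °C in the south to Tmin 5/Tmax 15 °C in the north in
January.

The true performance curve is a two-sided power function
v(T) = peak·((T−T_low)/(T_opt−T_low))^a · ((T_high−T)/(T_high−T_opt))^b
with b = a·(T_high−T_opt)/(T_opt−T_low) so the peak sits exactly at
T_opt — the standard left-skewed ectotherm shape. Defaults: zero
endpoints at the tolerance means (9.9, 39.2 °C), optimum 30 °C, peak
1 m/s, shape a = 2, velocity noise SD 0.05 m/s (5% of peak), ten
individuals. Preference series wander as AR(1) (coefficient 0.9,
SD 2 °C) around a 32.8 °C target; tolerance limits are normal draws
(CTmin 9.9 ± 2.0, CTgape 39.2 ± 1.4 °C) with ordering enforced by
redraw.

What passing tests show — and don't. The generator provides exact
ground truth, so the tests demonstrate *internal* correctness:
velocities, Q10s, curve optima and preference targets are recovered;
the cold-run counter equals brute-force enumeration; the hourly model
matches an independent transcription of its equations; the projection
respects its structural invariants. The generator does **not** emulate
real interpolated-grid error structure, coastal or microclimate
effects, radiative heating of basking animals, or behavioural
thermoregulation, so passing tests do not validate the ecological
accuracy of any particular real-world projection.

## Problem sizes

The default test and example configurations use a 20×20 grid × 3
winters for full projections (about 1.5 s) and smaller grids for
per-module tests; 1,000 random 63-day series back the cold-run oracle
check. These sizes give stable statistics for every property tested
while keeping the whole suite fast to iterate on.

## Known limitations

- CTgape is a behavioural heat-stress proxy, not a locomotor CTmax;
  the upper anchor inherits that interpretation.
- Fixed thresholds ignore acclimation within a winter.
- The hourly model is deterministic given (Tmin, Tmax, solar times);
  real diel curves vary with cloud and wind.
- Only regular lat/lon grids are supported (no reprojection), and
  raster I/O is NetCDF.
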