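# Methods

## The problem

The NWS heat index (HI) is the standard U.S. apparent-temperature measure
for summer heat stress, a function HI(T, RH) of near-surface air
temperature and relative humidity.  Given hourly station data, the true
daily maximum is

    hismax24 = max over the day's hours of HI(T_h, RH_h),

but many archives (notably daily climate-model output) only provide the
daily extremes, forcing the approximation

    hismaxest = HI(tasmax, hursmin),

i.e. one evaluation at the daily maximum temperature and daily minimum
relative humidity.  This package quantifies the behaviour of that
approximation: when it is exact, how it fails, how badly it undercounts
*extreme heat days*, and how that undercount scales with local heat
climatology.

Because RH at the hour of `tasmax` can only be at or above `hursmin`, and
HI increases with RH at fixed T, `hismaxest <= hismax24`: the estimate can
be exact or an underestimate, never an overestimate.  (See "the 81 degF
kink" below for the one caveat.)

## The heat index implementation

`hi_core.nws_heat_index` implements the operational NWS procedure
(Rothfusz 1990 regression as published by the NWS Weather Prediction
Center):

1. `T <= 40 degF` returns `T` (identity rule);
2. otherwise the simple formula
   `0.5*(T + 61.0 + (T-68.0)*1.2 + RH*0.094)` is returned when its mean
   with `T` is below 80 degF;
3. otherwise the nine-term polynomial applies, with a dry-air subtraction
   (`RH < 13 %`, `80 <= T <= 112 degF`) and a humid addition
   (`RH > 85 %`, `80 <= T <= 87 degF`).

The coefficients were validated against an independent term-by-term
evaluation whose results are frozen in the unit tests (e.g.
`HI(96.8 degF, 50 %) = 109.6459510648 degF`).

**The 81 degF kink.**  The operational procedure is *not* globally
monotone: at `T = 81 degF` the hand-off from the simple formula to the
polynomial-plus-dry-adjustment makes HI drop by about 1.07 degF as RH
rises from 4 % to 5 %, and by up to ~0.7 degF as T rises from 81 to
82 degF at `RH <= 5 %`.  This is a property of the published algorithm
(any faithful implementation reproduces it), confined to
`T` in roughly (80, 82) degF at `RH < 13 %`.  Two consequences:

* the RH-monotonicity property on the full integer grid fails at exactly
  that one grid step, and the corresponding acceptance test is left
  failing rather than smoothing the published procedure;
* in principle `hismaxest` could *exceed* `hismax24` by under ~1 degF on
  a day whose temperature maximum sits near 81 degF with hourly RH values
  below ~14 % — conditions far drier than anything the synthetic
  generator produces, and irrelevant to extreme-day counting (the kink
  sits 20+ degF below typical thresholds).

The largest adjacent-step discontinuity across the branch switch measures
1.31 degF on a 0.25-unit scan grid, inside the documented 1.5 degF bound.

Humidity conversions use the Magnus saturation vapor-pressure form with
the Alduchov–Eskridge constants (a = 17.625, b = 243.04 degC,
es0 = 6.1094 hPa), accurate to a fraction of a percent over the
meteorological range; the constants are keyword-swappable.  The Steadman
validity screen ships as an editable `(temperature, max valid RH)` table;
the published discussions of where the underlying thermoregulation model
becomes unphysical do not print an exact boundary, so the bundled table
is a best-effort approximation that only excludes extreme hot-humid
combinations.

## Synthetic weather generator

The generator emulates only what the comparison is sensitive to: the
relative timing of the temperature peak, RH minimum and HI peak.

* Temperature: seasonal Tmin/Tmax cycles (cosine over the year, peak at
  day-of-year 200) plus a shared daily AR(1) "synoptic" anomaly
  (sd 2 degC, lag-1 0.7), a raised-cosine diurnal shape peaking at 14 h
  local, and hourly AR(1) noise (sd 0.6 degC, lag-1 0.8).
* Dew point: a day-constant baseline (daily Tmin minus a 3 degC
  depression by default) plus its own hourly AR(1) noise
  (sd 1.5 degC) — within-day humidity variability is what gives cool
  stations their small but non-zero extreme-day miss rates — modified per
  regime: `surge` adds an evening logistic ramp (default 12 degC
  amplitude centred at 18 h, width 1 h), `drydown` a midday Gaussian dip.
  Dew point is clipped to the concurrent temperature; RH follows from the
  Magnus form, so RH is in [0, 100] by construction.
* Regime mixture: 70 % coupled / 20 % surge / 10 % drydown per day.
* Missingness: independent per hour (2 % default) with an optional
  block-outage mode (off by default).

Defaults describe a mid-latitude humid station (summer daily maxima
around 32 degC).  The 5-minute output evaluates the deterministic signal
at each timestamp and linearly interpolates the hourly noise knots, so
sampling at minute zero reproduces the hourly series exactly — which in
turn makes the capture-window extraction testable against an oracle.

`simulate_network` sweeps warmth (default −11 to +3 degC on the seasonal
means) and moisture (dew-point depression shrinking toward 0.5 degC)
across stations so that JJA thresholds straddle 80 degF, emulating the
cool-dry-to-hot-humid span of a continental station network.

What the generator does *not* emulate: fronts and multi-day synoptic
structure beyond AR(1), radiation-driven diurnal asymmetry, wind, or
instrument error models.  Passing tests therefore show the *logic* of the
comparison pipeline is correct and that the documented regimes produce
the documented signatures; they do not certify magnitudes for any real
station.

## Aggregation conventions

* Day boundary: local standard time (ISD-Lite UTC timestamps are shifted
  by a per-station fixed offset before aggregation); daily extremes and
  "evening" semantics are local phenomena.
* Completeness: at least 18 of 24 valid hours (configurable); a strict
  24-hour rule would discard most real station-days.
* Extremum ties resolve to the earliest hour, applied identically to
  `tasmax`, `hursmin` and `hismax24` so the case taxonomy is
  well-defined.
* Capture window: for each clock hour the valid sub-hourly record nearest
  the top of the hour within ±15 minutes is taken; equal offsets resolve
  to the earlier record.

## Comparison procedures

* Direct comparison runs over complete May–September days; differences
  `hismax24 − hismaxest` fall into bins {0}, (0,1], (1,2], (2,3], >3 degF
  (the bin edges anchor on the 1 degF and 3 degF figures quoted in
  published summaries).  "Exact" uses a 1e-6 degF tolerance
  (configurable), absorbing floating-point noise while remaining far
  below the 0.1 K quantization of real archives.
* Threshold comparison: the station threshold is the 95th percentile
  (linear interpolation between closest ranks) of `hismax24` over
  complete June–August days; extreme-day membership is strict exceedance;
  the same `hismax24`-derived threshold is applied to both series.  The
  underestimation ratio `(N24 − Nest)/N24` is reported as missing when
  `N24 = 0`.
* NWS categories are half-open: Caution [80, 90), Extreme Caution
  [90, 103), Danger [103, 125), Extreme Danger [125, ∞) degF.
* Temporal cases: 1 — HI peak hour equals the RH-minimum hour (a
  sufficient condition for exactness on days warmer than the identity
  regime); 2 — equals the T-maximum hour only; 3 — neither (the evening
  moisture-surge signature).

## Two-part underestimation model

Station-level underestimation `r` versus JJA threshold `h` (degF):

    r(h) = c                    for h < 80
    r(h) = c * exp(k * (h-80))  for h >= 80

`c` is the arithmetic mean ratio over stations below 80 degF (reported to
2 decimals; full precision retained internally); `k` is found by bounded
scalar least squares on the ratio scale (log-scale loss available behind
a flag; ratio-scale is the default to avoid distortion near small
ratios).  The exponential with a hard continuity constraint at the
80 degF breakpoint is the minimal one-parameter family consistent with a
flat branch meeting a nonlinearly rising branch; the published account
names an exponential fit with that intersection constraint but prints no
formula, so this parameterization is this package's own choice.
Predictions clip to [0, 1].  On the bundled 37-station table the fit
gives c = 0.06 (mean 0.05525 over the four sub-80 stations) and
k ≈ 0.076 per degF.

Grid application is element-wise prediction over a Fahrenheit-labelled
`xarray.DataArray` (NaN propagates); the `offset_f` argument is a
declared placeholder for dataset-specific threshold calibrations, default
0.

## Numerical and testing choices

* Problem sizes: property tests use 1–3 year synthetic stations; the
  bounded-estimate check pools two 14-year stations (~10,200 complete
  days); the network sign test uses 12 stations × 3 years × 5 seeds; the
  rate-recovery check uses 20 seeds of 34 synthetic summary rows.
* All randomness flows from explicit integer seeds;
  `numpy.random.default_rng` children are derived via `SeedSequence`.
* The k optimizer is bracketed on [−0.5, 0.5] per degF (an order of
  magnitude beyond plausible rates) with 1e-10 tolerance, and a unit test
  confirms the optimum beats a 401-point grid scan.

## Known limitations

* The Steadman validity polygon is approximate (see above).
* The generator's miss rates and case fractions are qualitative
  emulations, not calibrated to any station.
* The exact-match statistic of real 0.1 K-quantized archives may depend
  on the archive's rounding; the tolerance is exposed for that reason.
* ISD-Lite and USCRN parsing covers the documented temperature/humidity
  columns only; pressure, wind and precipitation fields are ignored.
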