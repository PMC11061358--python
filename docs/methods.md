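# Methods

This note documents the models implemented in `plumchill`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Thermal-time models

All four models consume hourly temperatures in °C.

**Chilling Hours (Weinberger).** 1 CH per hour with `0 ≤ T ≤ 7.2 °C`, both
boundaries closed.

**Chilling Units (Utah).** The published band edges leave 0.1 °C slivers
undefined (…9.1 / 9.2…, …12.4 / 12.5…, …15.9 / 16…). We implement
contiguous half-open bands, closed on the left, with breakpoints at 1.5,
2.5, 9.2, 12.5, 16.0 and 18.0 °C and weights 0, 0.5, 1, 0.5, 0, −0.5, −1.
This honours every printed boundary while making the lookup total.
Negative-band magnitudes (−0.5 then −1.0) follow the original Utah model.
Cumulative CU is *not* clamped at zero — the convention of the common
chill-modelling toolchain — but `accumulate(..., clamp_cu=True)` is
available.

**Chilling Portions (Dynamic model).** Two-step kinetics: each hour the
intermediate `x` relaxes toward its temperature-dependent equilibrium
`x_s(T)` at rate `k1(T)`,

    x ← x_s − (x_s − x)·exp(−k1),   k1 = A1·exp(−E1/T_K),
    x_s = (A0/A1)·exp(−(E0−E1)/T_K),

and when `x ≥ 1` the fraction `ξ(T) = sr/(1+sr)` with
`sr = exp(slope·T₁·(T_K−T₁)/T_K)` converts irreversibly to portions and is
removed from `x`. The kinetic constants are the standard published set
(slope 1.6, T₁ = 277 K, A0 = 1.395·10⁵, A1 = 2.567·10¹⁸, E0 = 4153.5,
E1 = 12888.8), exposed through `DynamicModelConstants` — the de-facto
parameterization of the cited model and of the tooling built on it.
The implementation is vectorized across replicate series (the per-hour
recursion is sequential by nature); tests check it against an independent
scalar transcription of the recursion to 1e-9.

**Growing Degree Hours (Richardson).** `max(0, min(T, 25) − 4.5)`; hours
above 25 °C count as 25 °C, so an hour contributes at most 20.5 GDH.

**Windows.** Time is local standard time without DST. Accumulation windows
are inclusive of the start date's hour 0 and the end date's hour 23.
Split accumulations add exactly for CH/CU/GDH; for CP the Dynamic-model
state must be carried across the boundary (`initial_state=`), and tests
assert the carried result equals a single pass.

## Hourly temperatures from daily extremes

Scenario winters exist only as daily Tmin/Tmax, so an idealized day-curve
supplies the hourly values: a quarter-sine rise from Tmin at sunrise to
Tmax in early afternoon (at `sunrise + (daylength + 4)/2`, the classic
sine–logarithmic convention), then a logarithmic night-time decay toward
the next day's Tmin at the following sunrise. Daylength comes from
standard solar geometry (Cooper declination; latitude restricted to
±66°). Two numerical choices matter:

- Sunrise and time-of-maximum are snapped to the hourly grid, and
- each day's 24 sampled values are affinely rescaled so the sampled
  minimum and maximum equal that day's Tmin/Tmax exactly.

Without the rescaling, hourly sampling of any continuous curve misses the
extremes by up to ~0.2 °C whenever consecutive days' extremes differ; the
affine correction is typically the identity (the anchor hours already
attain the extremes) and only redistributes a few tenths of a degree on
days with sharp warm/cold fronts. Semi-hourly station records are
averaged to hourly means; gaps up to 6 h are filled linearly, longer gaps
are errors naming the span.

## Endodormancy release, bloom, requirements

ER is the first sampling date whose *mean* day-8 bud weight is ≥ 1.3× the
mean day-0 weight — means of the ~10 weighed buds, not a per-bud vote,
because the release criterion concerns the collective weight gain of the
sampled buds. ER is reported as the sampling date itself (weekly
resolution, no interpolation). F50 is the first date with ≥ 50 % flowers
open. CR is `accumulate` over [Oct 1, ER]; HR starts the day *after* ER
(so ER-day hours are not double-counted as heat) and includes all of F50.
CR classes use the CP ≤ 30 / 31–40 / ≥ 41 bands (CH: 300/501, CU:
500/701); the consensus class is the CP label, since the Dynamic model
shows the lowest between-year variability in warm-winter regions;
disagreement between models is flagged rather than hidden. Fractional
values between the printed integer bounds fall into the middle band.

Summary statistics: CV% = 100·sd/mean with sample sd (n−1); a single
season reports sd and CV as missing. Kruskal–Wallis (tie-corrected,
chi-square approximation) and the Spearman correlation network delegate to
`scipy.stats` behind this module's interface; all-identical samples return
a flagged degenerate result instead of an error. Dates enter the
correlation analysis as days since October 1st of their dormancy season.

## Climate scenarios and the weather generator

Historic scenarios are 15-year running means (centred, edges truncated
with a warning) of per-(year, month) means of daily extremes, for
reference years 1980–2020 by default. Future scenarios carry GCM-table
rows through unchanged, one scenario per (GCM, RCP, horizon).

The multi-site vector-autoregressive generator used in comparable studies
is replaced by a deliberately simple single-site bivariate AR(1): its only
role here is to dress monthly means in realistic daily variability.
Calibration subtracts a smooth seasonal cycle (periodic cubic spline
through the record's mid-month monthly normals) and estimates, per
calendar month: residual sd of Tmin and Tmax, their residual correlation,
and lag-1 autocorrelations (consecutive-day pairs only). Simulation
interpolates the scenario's monthly means with the same periodic spline —
avoiding step discontinuities at month boundaries — and adds standardized
AR(1) anomalies `z_t = ρ z_{t−1} + √(1−ρ²) ε_t` with Tmin/Tmax
innovations correlated per month. `Tmin ≤ Tmax` is enforced by swapping,
and swap counts are logged. Mid-month spline anchoring reproduces monthly
means up to a small curvature bias (≲ 0.1 °C for a sinusoidal annual
cycle); tests allow 3 standard errors plus 0.15 °C for it. Scenarios whose
month-to-month profile is non-periodic or discontinuous will overshoot at
the year wrap — monthly *normals* are the intended input.

Chill availability is the Dynamic-model CP total per replicate winter
over Oct 1 – Feb 18. The Feb 18 end (the earliest cultivar's first
flowering date) is the default; the window is configurable (e.g. Feb 13,
the alternative flowering-date convention for these regions).

## Fulfillment risk

The requirement uncertainty is propagated by drawing 1000 values "within
mean ± sd". The draw distribution is not uniquely determined by that
phrase; we default to uniform on the interval (a truncated normal at ±1 sd
is available via `distribution="truncnorm"`). Uniform draws are
*stratified* (one draw per 1/n-quantile stratum, jittered within the
stratum): the marginal distribution is unchanged but the Monte-Carlo error
of the reported median collapses from ~0.01–0.03 to below one empirical
step of the exceedance curve, and tests hold the sampled median to a
fine-grid brute-force oracle within 0.02. Exceedance is inclusive
(chill availability equal to the requirement counts as fulfilled) to avoid
knife-edge nondeterminism. With sd = 0 the result is exactly the empirical
exceedance fraction. `risk_matrix` uses common random numbers across
cultivars so the matrix is monotone in the requirement mean, orders
cultivars by CR, and reports 5th/95th percentile bands; a median
probability ≥ 80 % is labelled low-risk.

## Synthetic data: what it emulates, what it does not

**Station records.** Daily mean cycle
`mean − amplitude·cos(2π(doy−15)/365.25)` (coldest mid-January), Tmin/Tmax
at ± half the diurnal range, plus a *shared* AR(1) anomaly (perfectly
correlated between Tmin and Tmax) and small independent jitter
(0.2 °C sd). The shared-anomaly design gives the generator calibration a
known truth to recover (lag-1 ρ, residual sd, near-unit Tmin–Tmax
correlation). Two presets are calibrated to the study regions' monthly
normals: `BADAJOZ_LIKE` (annual mean 16.8 °C, amplitude 7.8 °C → January
≈ 4/14.5 °C) and `ZARAGOZA_LIKE` (15.0 °C, 9.0 °C → January ≈ 1/11 °C),
with anomaly sd 2.0–2.2 °C and ρ = 0.7, typical of Iberian daily
temperature series. Not emulated: heteroscedastic seasons, skewed cold
snaps, heat waves with intra-day structure, precipitation coupling, or
multi-station correlation. One consequence: the idealized day-curve and
symmetric anomalies make synthetic winters somewhat more chill-effective
than the corresponding real stations, so absolute CP totals run higher
than observed regional values; all cross-scenario and cross-region
*contrasts* — which is what the acceptance properties assert — are
unaffected by this level shift.

**Forcing experiments.** Per-bud day-0 weights `N(0.02 g, noise_sd)`;
day-8 weights are the day-0 weight times 1.05 before the true release
date and times 2.0 on/after it, plus independent noise. The bud-weight
measurement error is an assumption (default 0.002 g ≈ 10 % of the bud
weight; the recovery study uses 0.003 g), not an inference from published
data. The step-multiplier design makes the 30 % rule identifiable; real
buds show a more gradual pre-release drift.

**Bloom curves.** Logistic fraction-open with a 3-day scale, observed
every 2 days; optional truncated Gaussian observation noise.

**GCM tables.** Baseline monthly normals plus an RCP/horizon warming
delta plus a per-GCM offset drawn once (sd 0.5 °C) and reused across
months, RCPs and horizons — mimicking systematic between-model bias.
Default deltas (RCP4.5: +1.4 / +1.9 °C, RCP8.5: +2.0 / +4.3 °C for
2050/2085) follow the magnitude ordering of the two pathways for
mid-latitude Europe. No bias correction, no month-dependent warming, no
real GCM output parsing.

## Problem sizes

Defaults follow the study design: 100 replicate winters per scenario,
1000 requirement draws, 15 pseudo-GCMs × 2 RCPs × 2 horizons = 60 future
scenarios, weekly forcing sampling of 10 buds. The test suite exercises
the same code paths at reduced ensemble sizes (4–100 replicates, 1–2
GCMs, 16–40-year records) chosen so the whole suite runs in well under a
minute while keeping every statistical check at ≥ 3-standard-error
resolution; the release-date recovery study uses the full 500 replicate
experiments.

## Known limitations

- ER is resolved only to the weekly sampling grid, as in the field
  protocol; CR inherits that quantization.
- The AR(1) generator does not reproduce multi-day blocking episodes or
  the cross-site structure a vector-autoregressive generator would give.
- The day-curve assumes clear-sky-like diurnal shapes; overcast days with
  flat profiles are not represented.
- Chill models are applied to hourly *means* when the input is
  semi-hourly; sub-hourly model evaluation is out of scope, as are
  alternative chill models (North Carolina, Positive Utah).
- Classification bands are step functions of the requirement mean;
  cultivars near a boundary can change class between seasons. The class
  disagreement flag should be consulted before relying on the consensus.
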