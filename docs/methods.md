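# Methods

`ozflux` estimates how much of the ozone deposited onto a crop canopy enters
through stomata — the phytotoxic pathway — from half-hourly eddy-covariance
observations, and converts that partition into flux-based dose (POD6) and
concentration-based exposure (AOT40, W126) metrics. This note records the
models, the assumptions behind them, and the design choices that were
genuinely open.

## The resistance network

Total O3 deposition is described as three resistances in series between the
measurement height and the ground: aerodynamic (Ra = u/u*²), quasi-laminar
boundary layer (Rb = 2/(k·u*)·(Sc/Pr)^(2/3), with Sc/Pr the ratio of thermal
diffusivity 0.2 cm² s⁻¹ to gas diffusivity, 0.14 cm² s⁻¹ for O3), and a bulk
surface resistance Rc. With the surface concentration taken as zero,
Vd = FluxO3/[O3] measures the whole network, so Rc = 1/Vd − Ra − Rb follows
by subtraction. Rc in turn is two parallel conductances — stomatal (Gs,O3)
and non-stomatal (Gns,O3; cuticular destruction and soil uptake) — and the
analysis' job is to split them. Ra is used exactly in the u/u*² form with no
stability correction. Records where 1/Vd < Ra + Rb (negative Rc) are flagged
and excluded from conductance work, as are negative-Vd records.

Assumptions: a single big-leaf surface, no within-canopy transport, no
storage, surface O3 concentration zero. The Obukhov length uses the standard
L = −ρ·cp·u*³·T/(k·g·H) definition with displacement height d = 0.67·h_canopy;
it feeds only the stability diagnostic ζ = (r−d)/L, not the resistances.

## Two routes to stomatal conductance

**Penman–Monteith inversion.** The evaporation-resistance form of
Penman–Monteith is solved for the surface resistance to water vapor,
Rc,H2O = ρ·cp·VPDcan/(γ·λE) − Ra − Rb,H2O, using the canopy-to-air vapor
pressure deficit VPDcan = es(Ts) − e_r with Ts diagnosed from the sensible
heat flux (Ts = Tair + H·(Ra+Rb,heat)/(ρ·cp)). Surface conductance equals
stomatal conductance only when λE is mostly transpiration, so records are
kept only outside rain events and a trailing 36 h window, with solar zenith
angle < 85°, and RH < 80% (all strict inequalities; the rain window and RH
cut are the two knobs of the sensitivity grid). Non-positive λE, VPDcan, or
inverted resistance excludes a record with a reason code.

**Medlyn model.** Stomatal conductance is also modelled from photosynthesis:
Gs,H2O = G0 + 1.6·(1 + G1/VPDcan)·GPP/Ca, with GPP from nighttime-based NEE
partitioning and Ca = 420 µmol mol⁻¹ by default. (G0, G1) are fitted to the
PM estimates by bounded nonlinear least squares (G0, G1 ≥ 0, trust-region
reflective, p0 = (0.01, 2.0)) in consecutive 10-day windows aligned to the
first valid date; windows with fewer than 20 valid half-hours emit no fit. A
season-wide single fit is available for the sensitivity analysis's "fixed"
mode. The linear-VPD form is used as the primary model; a `medlyn_sqrt_vpd`
switch provides the original square-root variant. Fitting happens in
mol m⁻² s⁻¹; conversion to m s⁻¹ uses the ideal-gas molar density of air at
measured T and P.

Both H2O conductances scale to O3 by the diffusivity ratio 0.61. The ratio
Gs,O3/Gc,O3 (Gc,O3 = 1/Rc,O3 from the measured network) must fall in the
closed interval [0, 1] for a record to be retained; the stomatal O3 flux is
then ratio·Vd·[O3].

## Carbon partitioning

Nighttime NEE (solar elevation ≤ 0) is taken as respiration. A
friction-velocity threshold guards against under-measured calm-night fluxes:
per calendar month, restricted to 19:00–03:00, a continuous two-segment
piecewise-linear model of NEE against u* is fitted over a 40-point grid of
candidate breakpoints (5th–95th percentile span) by least squares; the
maximum across months is the threshold. A month's breakpoint counts as
unreliable when it lands on the grid boundary or improves on a single
straight line by less than 5% of SSE; an unreliable season-level result
leaves the data unfiltered rather than discarding records on noise.

Gaps are filled by a look-up-table scheme: the mean of records within
|ΔSW_IN| ≤ 50 W m⁻², |ΔTA| ≤ 2.5 °C, |ΔVPD| ≤ 0.5 kPa in a ±7 then ±14 day
window, falling back to the same-half-hour diurnal mean; every filled value
carries a flag. This deliberately simplifies full Marginal Distribution
Sampling to its first lookup tier.

Respiration follows Lloyd–Taylor,
Reco = Rref·exp(E0·(1/(283.15−227.13) − 1/(T_K−227.13))). E0 is estimated
once per series on all nighttime records (bounds 30–450 K); Rref is
re-estimated in 15-day windows by linear least squares with E0 fixed, and
interpolated in time between window centres for daytime extrapolation.
GPP = Reco − NEE, clipped at zero with the clip count recorded.

## Dose and exposure metrics

Daily POD6 integrates daytime stomatal flux above 6 nmol m⁻² s⁻¹:
Σ max(0, F_s − 6)·1800, reported in µmol m⁻². AOT40 sums half-hourly
exceedances over 40 ppb; W126 applies the sigmoid weight
1/(1 + 4403·e^(−126·[O3]/1000)) per sample. Both are accumulated per
half-hour sample without a 0.5 h weight (the half-hourly dialect); an
hourly-mean dialect first averages the two half-hours of each clock hour and
— because max(0, x−40) is convex — can only lower AOT40. "Daytime" is solar
zenith < 90° by default. A day's metric is emitted only with ≥ 5 valid
samples. Seasonal accumulation reports three day sets: all
concentration-valid days, and the intersections with days where each POD6
estimate exists, so exposure and dose can share a day basis.

Diurnal centroids are value-weighted mean hours, Σv·t/Σv, over the 07–17
daylight window (09–17 as an alternative), requiring ≥ 9 valid points and
non-negative weights; a centroid past 12 marks afternoon-shifted activity.

The sensitivity grid crosses 5 post-rain windows (24–72 h) with 3 RH
thresholds (70/80/90%) — 15 filters — and runs each with moving (10-day) and
fixed (season-wide) Medlyn parameters: 30 cells, with min/max bounds and the
moving-vs-fixed difference reported.

## High-frequency processing

The 10 Hz path despikes each channel with a moving-window median/MAD filter
(5-min window, 6 MADs — the algorithm and thresholds are conventions, not
facts about any particular site), double-rotates the wind vector (yaw then
pitch; means of v and w forced to zero, per-sample magnitudes preserved),
and computes covariance fluxes of deviations from block means.
λE = λ·M_H2O·cov(w, c_H2O)·10⁻⁶ with the exact µmol→mol conversion; a
`literal_eq3` flag reproduces a 10⁻³ variant that appears in print but is
unit-inconsistent. Sonic temperature stands in for air temperature in the
heat flux without humidity correction, and no WPL density correction is
applied by default. Quality control: the steady-state test compares the mean
of six 5-min sub-covariances to the 30-min covariance (≤30% class 0, ≤100%
class 1, else 2); the integral-turbulence test compares σw/u* to the neutral
surface-layer value 1.3 with the same bands. Half-hours with more than 10%
missing samples (strictly more — exactly 10% is kept) or any class-2 flag
are dropped, with removal bookkeeping.

## The synthetic world

The generator exists so that every stage has ground truth. It produces:
clear-sky shortwave from NOAA solar geometry scaled by per-day cloud factors
and a humid-morning haze attenuation (25% at 08:00, σ = 2 h) that emulates
the slow burn-off of the midwestern summer boundary layer; air temperature
lagging radiation (peak 15:00, ±6 °C); RH moving opposite temperature;
Poisson rain events (0.2 day⁻¹) that dim the sun and push RH up; calm nights
and breezy days (nocturnal u* straddling the weak-turbulence regime); an
afternoon-peaking O3 cycle (25 ppb base + 25 ppb Gaussian bump at 14:00,
σ = 3 h, floored at zero — the bump shape is a stand-in, configuration
exposed, since no parametric diurnal form is standard); GPP from a
rectangular-hyperbola light response with a C4 temperature modifier
(+8%/K around 22 °C — C4 assimilation roughly doubles from 18 to 30 °C below
its thermal optimum, and this is what sustains afternoon conductance);
Lloyd–Taylor respiration (Rref = 2.0 µmol m⁻² s⁻¹, E0 = 200 K); Medlyn
stomatal conductance with G0 = 0.02 mol m⁻² s⁻¹, G1 = 3.0 kPa; a constant
non-stomatal O3 conductance 0.002 m s⁻¹ (0.2 cm s⁻¹); and the full
resistance network run forward to O3 flux.

The energy balance is closed by construction (available energy
A = 0.65·SW_IN − 20 W m⁻², H = A − λE), and the canopy VPD is solved to a
damped fixed point of the coupled Medlyn/Penman–Monteith/surface-temperature
system, so the analysis' inversion recovers the truth to machine precision
on a noiseless season. Observation noise is multiplicative Gaussian on
fluxes (5% default), additive on temperature (0.2 °C), multiplicative on O3
(5%); all draws come from one seeded generator and identical seeds give
byte-identical output. Truth goes to a sidecar table only. An optional
nighttime u*-suppression (FC damped by min(1, u*/0.09)) emulates the
weak-turbulence bias the friction-velocity screen is meant to catch.

What the generator does *not* emulate — and what passing tests therefore do
not demonstrate about real towers: energy-balance non-closure, advection and
storage, spectral attenuation of fluxes, instrument drift, soil-moisture
dynamics, senescence, footprint heterogeneity, and correlated (rather than
independent Gaussian) observation error.

## Numerical choices and degenerate inputs

- Magnus saturation vapor pressure 0.6108·exp(17.27·T/(T+237.3)) kPa;
  λ_v = (2.501 − 0.00237·T)·10⁶ J kg⁻¹; γ = cp·P/(0.622·λ_v); moist-air ρ
  and cp from partial pressures and specific humidity each half-hour.
- D_H2O = 0.249 cm² s⁻¹ for Rb,H2O (only the O3 and heat diffusivities are
  part of the network definition; the H2O value is the standard one).
- H = 0 maps to ζ = 0 (neutral) rather than a division by zero.
- Negative VPDcan (dew-like) excludes a record from fits but is not clipped.
- The Medlyn fit seeds at (0.01, 2.0); non-convergent windows are dropped.
- Change-point ties break toward the smaller SSE on a fixed 40-point grid,
  making the estimate deterministic given the data.

## Problem sizes

The test suite runs seasons of 8–62 days (384–2976 half-hours) and 10 Hz
blocks of 2 000–18 000 samples; parameter-recovery checks use 20 seeded
30-day seasons. The acceptance script runs one 62-day season (2976
half-hours, matching a July–August study period) plus the 30-cell
sensitivity grid.

## Known limitations

- The LUT gap-filler is a declared simplification of MDS; under sparse
  similar-weather coverage it falls back to diurnal means, which damps
  variance.
- The u*-screen's 19:00–03:00 restriction follows the change-point
  convention; partitioning itself uses the astronomical night.
- Ra omits stability corrections by construction, so Rc absorbs any
  stability-dependent transport error.
- AOT40/W126 "ppb h" values follow the per-sample half-hourly dialect; use
  `dt_weight`-style hourly averaging (the `hourly_mean` dialect) when
  comparing against standards literature.
- Critical-level comparisons (yield-loss regressions) are out of scope.
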