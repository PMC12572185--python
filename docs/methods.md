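# Methods

This note documents the models and procedures `ringcast` implements, the
defaults it ships, the numerical choices behind them, and what the
synthetic-data world does and does not say about real data.

## Growth model

The core is a monthly, empirical model of wood formation. Monthly mean
temperature maps to a partial growth rate GrT through a trapezoid
(parameters T1 < T2 ≤ T3 < T4, all °C): zero at or below T1, linear to 1
at T2, optimal through T3, linear back to zero at T4. The upper limb is
the model's heat-decline extension — without it (T3, T4 → very large) the
trapezoid degenerates to the classic two-parameter rising ramp, and a
regression test pins that equivalence. Relative volumetric soil moisture
maps to GrM through a ramp (M1, M2, v/v). Photoperiod enters as GrE,
mean monthly daylength divided by the longest month's daylength (1 in
June at northern mid-latitudes); daylength comes from the standard
sunset-hour-angle geometry at mid-month day-of-year on a 365-day
calendar, with the hour angle clamped poleward of the polar circles.

The integral growth rate is GrINT = min(GrT, GrM) · GrE (growth follows
the most limiting of temperature and moisture, modulated by daylight).
Each month carries a limiting-factor label: `none` when both partial
rates are 1; otherwise `low_moisture` when GrM ≤ GrT (exact ties go to
moisture — deterministic, and ties have measure zero on real forcing),
else `low_temperature` or `high_temperature` depending on which side of
the optimum plateau the month's temperature lies.

The annual ring-width proxy is
TRW(y) = [ΣGrINT(y) + w·ΣGrINT(y−1)] / (1+w), with w ∈ [0, 1] the
previous-year weight. The (1+w) normalization keeps the proxy on the
[0, 12] scale for every w; correlations are scale-invariant, so it does
not affect calibration, but it stabilizes relative-ring-width
diagnostics across sites with different w. The first simulated year has
no predecessor; its proxy is the plain annual sum and is flagged, and
every consumer (calibration windows, pseudo-ring generation) skips it.

## Climate forcing

Potential evapotranspiration is Thornthwaite's monthly formula,
PET = 16·(L/12)·(N/30)·(10·max(T,0)/I)^a, with the daylength (L) and
month-length (N) corrections and the cubic exponent a(I). The heat-load
index I is computed separately for each calendar year by default (a
climatological variant is available and coincides with it on noise-free
forcing); an all-subzero year yields I = 0 and PET = 0 without division.
Temperatures are clipped at 0 °C before entering the index — the
standard convention; a sensitivity switch is not provided because the
clip only matters for months that produce no PET anyway.

Soil moisture is a single leaky bucket in relative volumetric units.
Per sub-step: evapotranspiration demand scaled by relative moisture
(E = PET·M/Mmax), fast runoff that grows steeply with saturation
(R = P·(M/Mmax)^m_th + linear term), slow drainage proportional to M,
and conversion from mm to v/v over a 1000 mm rooting depth. The
constants (Mmax 0.76, Mmin 0.01, α 0.093, m_th 4.886, μ_th 5.8, M0 0.2)
are the CPC-style defaults of the original VS-Lite distribution; the
model modification under study concerns the response functions,
autocorrelation and heat index, not the bucket, so those constants are
kept and are all overridable. The month is integrated in 4 explicit
sub-steps (configurable); one-step vs four-step runs differ by under 1%
on the test forcings, but sub-stepping softens the clip at the bounds.
Every monthly loss term and the clip correction are reported, so the
water balance ΔM·ρd + E + R + D − P + overflow = 0 is checkable to
float precision (the conservation test demands 1e-9 mm).

The annual climatic water balance CWB = ΣP − ΣPET classifies sites as
dry (≤ 200 mm), moderate (200–700 mm) or humid (> 700 mm).

## Chronology building

Ring widths are ratio-detrended: each tree's series is divided by a
penalized least-squares smoother (second-difference penalty — the
discrete cubic smoothing spline / Whittaker form). The penalty λ is set
in closed form from the smoother's transfer function
H(f) = 1/(1 + 16·λ·sin⁴(πf)) so that H = 0.5 at a 60-year wavelength:
the fitted curve absorbs all variance slower than the cutoff (the
ontogenetic trend) plus half the variance at the cutoff itself. Missing
rings (zeros in rwl input, read as absent with a warning) get zero
weight in the fit. The fitted curve is floored at 0.001 mm before
division. Site averaging is Tukey's biweight robust mean (tuning
constant 9·MAD with a tiny epsilon so that a zero MAD — e.g. ten equal
values and one outlier — still downweights the outlier rather than
collapsing to the arithmetic mean), iterated to convergence; two or
fewer values fall back to the median. The index is not re-centred:
ratio detrending already puts its mean near 1. Replication filtering
requires at least five trees with a ring in every year of 1961–1995.

Two properties of this detrending matter for interpretation. First, the
smoother's natural boundary conditions make it track the series near
its ends, so its effective frequency response is nominal only in the
interior — the response measurement in `experiments.py` therefore trims
one cutoff length from each end. Second, the chronology is a high-pass
filtered version of the underlying growth signal: on noise-free
synthetic rings the 1961–2020 chronology correlates about 0.96–0.999
with the generating ring-width series, not exactly 1, because the
spline removes half of the signal's own variance at the cutoff
wavelength (and the previous-year weight reddens the signal's spectrum
slightly). No fitted smoother can do better; this ceiling is inherent
to ratio detrending with a cutoff inside the analysis window.

## Calibration

Random search: parameter vectors are drawn uniformly within per-site
bounds (defaults: T1 ∈ [0, 9], T2 ∈ [9, 20], T3 ∈ [15, 30], T4 ∈
[22, 40] °C; M1 ∈ [0.01, 0.10], M2 ∈ [0.10, 0.50] v/v; w ∈ [0, 1];
Mcap ∈ [0.30, 0.80] v/v — spanning published priors for the classic
model plus a physiologically plausible heat-decline range); draws
violating the orderings are rejected and redrawn, which preserves
uniformity on the ordered region. Each draw is simulated and the draw
maximizing Pearson r against the chronology over the calibration window
(1961 to the chronology's last year; at least 15 overlapping years) is
kept, ties broken first-seen. The search is fully vectorized: PET is
parameter-independent and computed once; the bucket advances all
capacities simultaneously; the response functions broadcast over draws
(a regression test pins the batch path to the scalar `simulate`). Ten
thousand draws on a 129-year site take a few seconds on one core.
Significance uses t = r·√(df/(1−r²)) with df = n−2 and a Fisher-z 95%
interval. Because the best of 10,000 draws is selected, the nominal p
is optimistic under the null — the honest check is out-of-window
verification, which the stationarity test provides. Sites are
calibrated independently with per-site seeds (global seed plus a CRC32
hash of the site id).

The noise-free recovery experiment calibrates against the truth model's
own chronology (proxy scaled to mean 1) so that it measures what the
search recovers, separately from the detrending ceiling above; the full
rings-to-chronology path is exercised by its own test. Recovered
response curves are compared to truth as mean absolute deviation over
the range of forcing the site actually visits — thresholds the climate
never exercises (a heat limb never reached, a moisture ramp never left)
are unidentifiable in principle and excluded by construction.

## Scenario forecasting

Normal-period statistics (1995–2014) give per-calendar-month means and
empirical quantiles (linear-interpolation, the type-7 rule — the
dominant software default; the choice is visible only at the second
decimal on 20-year windows). Three 12-month climatologies are built per
scenario × bi-decadal period: mean (normal means + anomalies), cool-wet
(0.15 temperature / 0.75 precipitation quantiles + anomalies) and
warm-dry (0.85 / 0.25). Anomalies are additive °C and mm; negative
forecast precipitation is floored at 0 with a warning. Four scenarios ×
four periods × three kinds = 48 climatologies per site. Forecasts
replicate one climatology for 10 identical years and keep the last, so
the bucket state and the previous-year proxy term are equilibrated
(under constant forcing the fixed point is reached to 1e-9 well before
10 years; the spin-up length is therefore not a tunable in practice).
Nothing in this module is stochastic.

The synthetic anomaly tables warm by +1 °C and dry by −2 mm/month per
period step, scaled 0.4/0.6/0.85/1.0 across the four scenarios — i.e.
about +4 °C and −15% annual precipitation by 2080–2099 under the
strongest scenario, the realistic envelope for Central-European
mid-century-to-2100 projections. They are month-uniform; real anomaly
seasonality is out of scope.

## Diagnostics

Growth deficit: GD(m) = GrE(m) − GrINT(m) ≥ 0, the growth foregone
relative to the photoperiod potential, attributed by the month's
limiting label (cold = low temperature; drought = high temperature or
low moisture, aggregated) and standardized by ΣGrE so that realized
plus foregone growth account for the full potential exactly (the
conservation test demands 1e-12). Growth cessation is GrINT = 0 —
exact, since the trapezoid and ramp return hard zeros. The growing
season runs from the first month whose cumulative GrINT reaches 2.5% of
the annual total to the first month reaching 97.5%, at month
granularity (the model is monthly; no sub-month interpolation); a
zero-growth year is flagged degenerate. Peaks are strict local maxima,
with January and December compared against their single neighbour;
plateaus are not peaks. Relative ring width divides a forecast proxy by
the baseline-period mean (1.48 → +48%). The one-sample two-sided Welch
test compares a forecast value against the 60-year baseline sample
(t = (x̄ − forecast)/(s/√n), df = n−1, difference reported as forecast −
baseline with its 95% CI); it is a thin wrapper over scipy and is
pinned to it at 1e-10. The shift-rate utility converts months over
years to days per year at 30 days per month.

## Stationarity testing

The split-period transfer function: the usable window (1961 onward) is
halved; the model is calibrated on the first half only and predicts the
second; observed is regressed on simulated in each half and the
difference in slopes is bootstrapped (years resampled with replacement,
1000 draws by default), with verdict "stationary" when the 95%
percentile CI of the slope difference covers 0. Both series are
z-scored within each half before regression, making the slope
scale-free (it equals that half's correlation). This choice is
deliberate: a response-regime change typically decorrelates observed
from simulated growth *and* inflates observed variance, and on the raw
scale those two effects cancel almost exactly in the slope, leaving the
test blind; the standardized slope isolates the decorrelation. Halves
shorter than 15 years trigger a warning and an "abstain" verdict rather
than a forced call.

The size/power study (`experiments.stationarity_study`) fixes a
treeline-like humid site (mean 4.5 °C, amplitude 9 °C, 1000 mm/yr) with
truth ramp 0.5–9 °C, so the low-temperature response carries the growth
variance, and simulates a regime shift by displacing that whole ramp
+5 °C (cambial activation warming) in the verification half. Measured
at 100 replicates: stationary data passes 100%, the shift is flagged in
about 80%. Two constructions that look similar do *not* work, and the
reasons are informative: shifting T1 alone mostly steepens the ramp
while the variance-carrying months stay shared, so the regimes remain
correlated (r ≈ 0.6) and detection stays near 15%; and a truth outside
the calibration bounds makes the calibrated model a wide-ramp
compromise that tracks both regimes. With 30-year halves this test has
power only against shifts that re-assign which months drive growth.

## Synthetic world

The climate generator produces a July-peaking sinusoidal temperature
cycle plus iid Gaussian monthly noise (default sd 2.0 °C) and gamma
monthly precipitation (mean following a seasonality-weighted cycle
summing to the annual total; shape set so the CV is 0.5) — magnitudes
chosen to match Central-European monthly station series. Pseudo-observed
rings multiply the truth model's proxy by a negative-exponential age
trend A·exp(−t/τ) + c (defaults 2.0 mm, τ = 50 yr, 0.5 mm per unit
proxy — decaying on a scale the 60-year spline removes) and per-tree
lognormal noise (default sd 0.05 with 12 trees, giving inter-tree
correlation near 0.5 and an expressed-population-signal above 0.9, the
standard threshold for a usable chronology); a 0.001 floor keeps widths
positive in fully growth-less years. Recovery and round-trip
experiments generate climate from 1892 so trees are ~128 years old and
the 1961–2020 window sits in the latter part of each series, as in real
mid-European chronologies. Dendrometer traces interpolate monthly
GrINT to daily increments and add a zero-mean sinusoidal water
oscillation of seeded period (4–9 days) and amplitude; NDVI curves are
a double sigmoid at 16-day cadence (23 samples/yr). Everything is
deterministic under a fixed seed.

What passing tests show — and what they do not: the synthetic world has
no spatial covariance between sites, no trends or autocorrelation in
climate noise, no disturbance-driven growth releases, no species
differences, and observation noise that is lognormal-iid rather than
structured. Pipeline correctness, conservation properties, recovery of
identifiable parameters and the ordinal forecast patterns transfer to
real data; the specific correlation levels and detection rates do not.

## Numerical and interface choices

0-based month indexing internally, 1-based (Jan = 1) in all I/O. CSV
schemas: climate (site_id, year, month, temp_c, precip_mm), soil
moisture m_rel, chronology (site_id, year, index, depth), anomalies
(scenario, period, month, dtemp_c, dprecip_mm), climatologies and tidy
diagnostics keyed by (site_id, scenario, period, kind). Tucson/rwl
supports both the 0.01 mm (stop 999) and 0.001 mm (stop −9999)
dialects; series ids are limited to the format's 8 characters and the
writer refuses colliding truncations. NDVI crossings are linearly
interpolated between composites, with an exact-on-threshold sample
counting as the crossing. The pipeline orchestrator hashes every
artifact into a run manifest; a fixed config and seed reproduce
byte-identical outputs.

## Known limitations

Monthly resolution blurs sub-monthly drought quiescence and autumn
reactivation; no vapour-pressure-deficit forcing, chilling/forcing
phenology, frost damage, or mortality dynamics; Thornthwaite PET is
temperature-only and known to exaggerate warming-driven drying;
calibration is a point estimate (no posterior); the stationarity test
abstains rather than adjudicates on short records. Forecast skill
inherits the stationarity assumption the test can only weakly verify.
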