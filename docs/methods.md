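# Methods

`seasmort` analyses the seasonality of monthly death rates in stratified
vital-statistics data: when in the year mortality peaks and bottoms out, how
confidently a 12-month cycle can be claimed, and how the relative size of the
seasonal swing has changed over a multi-decade window. This note records the
models, the numerical choices, and what the synthetic validation studies do
and do not demonstrate.

## Rate construction

Deaths arrive as monthly counts per stratum (ten age bands × sex × cause
category × climate region). Two normalisations precede all analysis:

- **Month-length correction.** Each month's count is multiplied by
  `31 / days_in_month` (leap-year aware), putting every month on a standard
  31-day footing. Without it, February would appear ~10% less deadly than
  January from calendar arithmetic alone.
- **Population interpolation.** Yearly populations are anchored to July of
  each year and linearly interpolated to months; months before the first or
  after the last July are extrapolated linearly from the two nearest anchors.
  Interpolation is in month units with the anchor at the month of July as a
  whole; anchoring instead at July 1 would shift interpolated values by under
  0.1% and none of the downstream statistics visibly. Rates are per 100,000
  per standardised month.

Cause-of-death codes are mapped to ten leaf categories (cancers,
cardiovascular, chronic respiratory, respiratory infections, unintentional
and intentional injuries, perinatal, maternal, substance use, other) by an
ordered first-match-wins rule table over ICD-9/ICD-10 code ranges. The
shipped table uses GBD-style chapter ranges with explicit catch-all rules;
it is input data, not algorithm, and a user-supplied table overrides it.
Rollups are fixed unions: cardiorespiratory = cardiovascular ∪ chronic
respiratory ∪ respiratory infections; injuries = unintentional ∪
intentional. Unmapped codes fail loudly by default (`strict=True`);
lenient mode routes them to `other` with a log entry, because silent
misclassification is worse than failure. The nine-region map follows the
NOAA climate-region grouping of the 50 states; DC, absent from that
grouping, is assigned to the Northeast with Maryland.

## Wavelet detection of 12-month seasonality

Series are detrended by least-squares polynomial regression on the time
index (default degree 4, configurable 1–6; detection is insensitive across
this range, which the suite checks) and affinely rescaled so min → −1 and
max → +1. Rescaling makes spectral power comparable across strata whose
absolute rates differ by orders of magnitude. A constant residual maps to
all zeros.

The continuous wavelet transform uses a Morlet mother wavelet with central
frequency ω₀ = 6 — the standard geophysical convention, under which the
Fourier period is ≈ 1.03 × scale, so the period axis reads directly in
months. The transform is computed in the frequency domain on the series
zero-padded to the next power of two, over a dyadic period grid from 2 to
72 months with 12 voices per octave (fine resolution near the 6- and
12-month bands). The cone of influence marks, for each time point, the
largest period whose estimate is untouched by edge effects, using the
e-folding distance √2·scale.

Significance of annual seasonality is a simulation test. The statistic is
the time-averaged power at the grid period nearest 12 months, restricted to
times inside the cone. The null ensemble is Gaussian white noise of the same
length passed through the *identical* preprocessing and transform; with
`n_sims` simulations (default 100) the p-value is the plus-one estimator
`(1 + #{null ≥ observed}) / (1 + n_sims)`, which is never exactly zero and
attains 1/101 at best for the default. White noise is the default null;
an AR(1) (red-noise) null is available behind a flag in principle via the
same machinery but is not a default because the headline test is against
white noise. Per-time diagnostics are exposed through the long-format power
export; the headline test is the whole-window statistic.

Operating characteristics verified by the suite: the empirical type-I error
on 500 pure-noise series lies within 3 binomial SEs of 0.05; a planted
12-month signal at relative amplitude 0.1 with ~200 deaths/month is detected
(p ≤ 0.05) in ≥ 90% of replicates over a 37-year window; a 6-month-only
signal leaves the 12-month band non-significant (its band power after
rescaling is far below the white-noise null's).

## Timing: centre of gravity on the circle

Months sit at 12 equally spaced angles, θ = 2π(m−1)/12, so December
neighbours January. The centre of gravity is the weighted circular mean

  θ̄ = arg Σⱼ wⱼ exp(iθⱼ),

with each (year, month) cell one observation weighted by its death rate;
it estimates the timing of maximum mortality. The negative centre of gravity
weights each month by the shortfall of its rate below that year's maximum
(the year's peak month gets weight zero) and estimates the timing of minimum
mortality. The normalised resultant length R̄ ∈ [0, 1] measures
concentration; circular variance is 1 − R̄. A zero resultant (flat series,
perfectly opposed weights) is an explicit undefined-mean signal — an
exception, never a silent 0 or NaN.

Pooling every (year, month) cell is the default because the defining
complex sum runs over deaths; an alternative that averages per-year mean
directions with equal year weights is available (`per_year_average=True`)
and agrees closely on stable signals (checked in the suite). Weights are
rates by default; passing a count series gives the count-weighted variant.

Confidence intervals are percentile bootstrap intervals on shortest-arc
angular deviations from the point estimate, resampling **calendar years**
with replacement (1000 replicates by default). The year is the resampling
unit because within-year months are strongly dependent through the seasonal
cycle itself; resampling months would destroy the very structure being
estimated. Replicates with undefined means are dropped; more than half
undefined is a hard failure with diagnostics. Simulated coverage at the
defaults (amplitude 0.2, ~500 deaths/month, 37 years) is within Monte Carlo
noise of the nominal 95%.

## Trend in the seasonal amplitude

For each calendar year the maximum- and minimum-rate months are found
empirically (after month-length correction; ties break to the earliest
month) — no month is presumed to be the seasonal peak, so summer-peaking
strata are handled identically to winter-peaking ones, unlike the
traditional Excess Winter Deaths index. The percent difference is
100·(r_max − r_min)/r_min (a max-denominator variant is available via
`denominator="max"`). Its standard error treats the two months' **raw**
counts as independent Poisson variables, by the delta method:

  se = 100 · (r_max / r_min) · √(1/d_max + 1/d_min).

Raw rather than corrected counts enter because the 31-day correction is a
deterministic rescaling; the Poisson variation lives in the raw count. The
delta form is validated against a parametric-bootstrap oracle in the suite.
Years with a zero minimum (undefined difference) or zero counts (infinite
variance) are excluded from fitting, never imputed.

The yearly differences are combined by weighted least squares on year with
weights 1/se². Because the weights are *known* Poisson variances, the slope
SE is taken from the fixed-scale (scale = 1) inverse-variance covariance —
fixed-effect meta-regression — rather than a residual-estimated scale, and
the slope p-value is the two-sided normal approximation. With the
residual-estimated scale the normal p-value over-rejects (~0.08 at nominal
0.05 in simulation); the fixed-scale form is calibrated (~0.04–0.05). The
fitted line evaluated at the window's first and last years gives the change
in seasonal difference over the window.

**Known limitation — small-amplitude selection bias.** When the seasonal
amplitude is small enough that several months lie within Poisson noise of
the true extreme (relative noise per month ≳ the rate gap between adjacent
months near the peak), taking the empirical max and min inflates the
percent difference. The inflation is similar across years when the
amplitude is stable or remains substantial, and so largely cancels in the
fitted *change*; but a decline toward near-zero seasonality at modest
counts biases the estimated change toward zero. The shipped recovery study
therefore emulates a young-male national stratum (~2,000 deaths/month)
whose seasonal difference falls from 55% to 30% — weakening but remaining
substantial — and recovers the planted 25-point decline within 3 SEs in
≈ 99% of replicates; the constant-amplitude type-I study runs at the
older-stratum scale (~20,000 deaths/month, amplitude 0.2) and rejects at
≈ 0.05.

## Synthetic data generator

The generator exists so every stage is testable without restricted
microdata. Monthly counts are Poisson with mean

  μ(y, m) = pop(y, m) · r₀ · e^{β(y−y₀)} ·
            (1 + Σₖ Aₖ(y) cos(2π(m − φₖ)/Pₖ)) · d(y, m)/31,

where pop(y, m) is the July-anchored interpolation of a deterministic
exponentially growing yearly population, r₀ a baseline rate per
person-month, β a log-linear secular trend, and each seasonal component has
period Pₖ ∈ {12, 6} months, relative amplitude Aₖ ≥ 0 and peak month φₖ.
An optional amplitude half-life halves Aₖ every H years (evaluated at
mid-month, so decay is smooth within years), emulating seasonality that
fades over the study period; the month-length factor reproduces the
calendar artefact the correction must remove. Configurations whose seasonal
components drive the mean negative in any month are rejected. Poisson noise
matches the Poisson SE model downstream; overdispersion is deliberately not
generated by default. A companion generator produces a four-times-daily
gridded temperature field — a regional sinusoidal annual cycle plus
independent Gaussian noise per sample — for the population-weighted regional
aggregation stage.

What the generator does **not** emulate: spatial correlation between
regions, within-month structure (day-of-week, heat waves, epidemics),
overdispersion, demographic drift between strata, or reanalysis physics.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated model, not robustness to every feature of real mortality
data — in particular, influenza epidemics make real winters heavier-tailed
than Poisson.

## Temperature aggregation

Sub-daily cell temperatures are averaged within cell-months (samples equally
weighted, month boundaries in local calendar time), then combined into
regional monthly means with population weights normalised within each region
(weights static over the window). Climatologies (per-month long-run means,
annual mean, annual range, warmest month) exclude incomplete years with a
warning. The temperature contrast between a stratum's peak- and
trough-mortality months uses the nearest-integer months from the timing
analysis.

## Reproducibility and problem sizes

All randomness flows through explicit seeds: a simulation seed and an
inference seed in pipeline configs, recorded with a config hash in the run
metadata; every validation study derives per-replicate seeds from one root
seed via `numpy.random.SeedSequence`. Re-running a config reproduces result
tables exactly.

The shipped validation studies use: 500 white-noise series (length 444,
100 null simulations each) for the wavelet type-I check; 30 replicates for
detection power; 200 replicates × 1000 bootstrap draws for CI coverage;
200 replicates for trend recovery and 500 for trend type-I. These sizes give
3-binomial-SE windows of about ±3 points on a 5% rate and ±4.6 points on
95% coverage and complete in about a minute on one core.
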