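# seasmort

Seasonality of all-cause and cause-specific mortality: monthly death-rate
construction, wavelet detection of 12-month periodicity, circular-statistics
timing of maximum and minimum mortality, and trends in the peak-vs-trough
percent mortality difference.

## Who this is for

Epidemiologists and biostatisticians working with stratified monthly death
counts (age group × sex × cause × region) and yearly populations — the shape
of national vital-statistics extracts — who want to answer three questions
per stratum:

1. **Is mortality seasonal?** A Morlet continuous wavelet transform of the
   detrended, rescaled rate series localises periodicity in time and period;
   the presence of 12-month seasonality over the whole window is tested
   against Gaussian white noise passed through the identical transform, with
   the plus-one Monte Carlo p-value `p = (1 + #{null ≥ obs}) / (1 + n_sims)`.
2. **When does it peak?** The centre of gravity of mortality is the weighted
   circular mean of months, `θ̄ = arg Σⱼ wⱼ e^{iθⱼ}` with months at 12 equal
   angles (December neighbouring January) and weights equal to death rates;
   the negative centre of gravity weights each month by its shortfall below
   the year's maximum and gives the timing of minimum mortality. 95% CIs come
   from a year-block bootstrap (1000 replicates).
3. **Is the seasonal swing changing?** Per year, the percent difference
   between the empirical maximum- and minimum-rate months,
   `100·(r_max − r_min)/r_min`, with a Poisson delta-method SE
   `100·(r_max/r_min)·√(1/d_max + 1/d_min)`, is fitted by inverse-variance
   weighted least squares on year; the fitted line gives the change in the
   seasonal difference across the window.

Rates are corrected to a standard 31-day month and use July-anchored linear
interpolation of yearly populations. Because the restricted microdata such
analyses usually require cannot be shipped, a synthetic-data generator
produces death, population and gridded-temperature tables with known planted
structure (Poisson counts, cosine seasonal components with optional
amplitude decay, month-length effects), so every stage is testable and its
operating characteristics measurable. See `docs/methods.md` for the full
model descriptions.

## Worked example

```python
import seasmort
from seasmort import circular, dataio, experiments, trend, wavelet

# a planted winter-peaking stratum: ~500 deaths/month, amplitude 0.2,
# peak in January, 1980-2016
series, counts, corrected = experiments.simulate_seasonal_stratum(
    baseline=500, amplitude=0.2, phase=1.0, seed=42)

res = wavelet.seasonality_test(series, n_sims=100, seed=1)
cog = circular.cog_analysis(series, n_bootstrap=1000, seed=2)
fit = trend.fit_weighted_trend(trend.yearly_percent_difference(series, counts))

print(f"p12 = {res.p12:.4f}")
print(f"peak month = {cog.max_timing.month:.2f} "
      f"(95% CI {cog.ci95_max.lo:.2f}-{cog.ci95_max.hi:.2f})")
print(f"trough month = {cog.min_timing.month:.2f}")
print(f"trend slope = {fit.slope:+.3f} %/yr (p = {fit.p_value:.2f})")
```

prints

```
p12 = 0.0099
peak month = 1.04 (95% CI 12.99-1.10)
trough month = 7.04
trend slope = +0.086 %/yr (p = 0.59)
```

The p-value 0.0099 = 1/101 is the smallest attainable with 100 null
simulations — the planted 12-month cycle is unambiguous. The recovered peak
(month 1.04 ≈ early January) and trough (7.01 ≈ July) match the planted
phase, with the CI wrapping across the December/January boundary. The trend
slope is indistinguishable from zero, as it should be for a constant planted
amplitude.

The same analysis runs end to end from a YAML config over many strata:

```
seasmort run -c config.yaml -o results/
seasmort report --run-dir results/
```

with stage subcommands (`simulate`, `rates`, `wavelet`, `cog`, `trend`,
`temperature`) for running pieces on CSV files.

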