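# Methods

This note records the models the package implements, the defaults it
ships, the numerical choices that matter, and what the synthetic tests
do and do not demonstrate.

## Radiocarbon calibration

A radiocarbon measurement y ± σ_lab (conventional 14C years BP, or F14C
for post-1950 samples) is compared with a calibration curve giving the
expected measurement μ(θ) and curve uncertainty σ_curve(θ) at calendar
age θ. The likelihood of θ is Gaussian with variance
σ_lab² + σ_curve²(θ). The posterior on an annual calendar grid assigns
each grid year the likelihood integrated over its one-year bin
(composite Simpson quadrature with 8 sub-intervals per bin, on the
linearly interpolated curve) and normalises to unit mass. Integrating
per bin rather than sampling the bin centre makes the discrete masses
agree with fine-grid numerical integration to better than 1e-6 total
variation, which is how the test suite checks them. Because curve knots
fall on bin centres, the curve's interpolation kinks land on Simpson
pair boundaries and do not degrade the quadrature order.

Highest-posterior-density sets are built greedily: grid years are
admitted in order of decreasing probability mass until the requested
coverage (default 0.683, the "1-sigma" convention) is reached, ties
broken toward earlier years for determinism, and contiguous runs merged
into inclusive intervals. On a non-monotone bomb curve the admitted set
naturally splits into disjoint intervals. Coverage is nominal only at
grid resolution: a 10-year uniform density needs 7 years to hold 68.3%.

The grid step is 1 calendar year, matching the annual resolution of
everything downstream. Queries outside the curve support are errors;
the posterior grid is trimmed half a bin inside the support so every
bin is fully covered.

## Age models

Chronologies are piecewise-linear maps from ring sample number
(1 = bark, increasing inward) to calendar year, anchored at tie points.
Tie points are *inputs*: reconciling shared climate signals across trees
is an expert decision with no objective function, so the package
supplies validation metrics for that loop rather than automating it.
Between tie points the growth rate is constant. A ring carrying two
years (larger year listed first) declares a growth hiatus: the mapped
year drops by the gap duration at that ring, the ring itself taking the
older (growth-arrest) year. Extrapolation beyond the terminal tie
points is an error by default; an explicit clamp mode exists and is
used when validating end-of-core dates.

Validation asks, for each calibrated date, whether the model year falls
inside the union of that date's HPD intervals, and reports the distance
to the nearest interval otherwise; dates flagged as outliers are listed
but excluded from summary fractions. With a correct chronology roughly
68% of dates should fall inside their 1σ ranges — the package treats
58–78% as the plausible band in its own coverage tests. Stratigraphic
inversion screening flags pairs of dates whose entire calendar ranges
are disjoint and in the wrong ring order, the signature of a labelling
error; overlapping ranges are never flagged.

No posterior is placed on ages and no error is propagated through the
age model — the anchors are treated as exact. The 21-year smoothing
downstream is what absorbs decade-scale dating error.

## Isotope corrections

Corrections are applied per tree, after dating, before smoothing.

**Suess normalisation.** δ_corr(t) = δ_meas(t) − (δ_atm(t) − δ_atm(ref))
with reference year 1748, the inflection between pre- and
post-industrial atmospheric change. Years at or before the reference
pass through bit-identically when the atmospheric record is flat before
it; fractional sample years interpolate the annual record linearly.

**Pre-industrial (pin) CO2 correction.** The C3 discrimination model
Δ = a + (b − a)·c_i/c_a links ring δ13C to the leaf state, with
diffusion and carboxylation endpoints a = 4.4‰ and b = 27‰ (the
standard values; configurable, since different calibrations exist).
From a Suess-corrected value the implied Δ and hence c_i are computed
at the year's actual c_a; the leaf state is then projected to the
reference c_a and the discrimination inverted back to δ13C. Two
projections are exposed:

* `constant_ci_offset` (default): c_i_pin = c_i − (c_a − c_a(ref)).
  The plant defends the c_a − c_i gradient; this is the active-response
  endpoint and yields the largest defensible correction. Projections
  driving c_i_pin ≤ 0 raise an error — they signal implausible inputs.
* `constant_ci_ca`: c_i_pin = c_i·c_a(ref)/c_a. The plant defends the
  ratio; Δ is unchanged and the correction is the identity.

The true plant response lies between these endpoints, and no published
consensus fixes it for baobabs, so the package brackets rather than
asserts: run both modes and report the spread. (A single blended
formula that floors the offset projection at the ratio projection was
considered and rejected: since c_i < c_a always, the ratio projection
dominates the offset projection whenever c_a exceeds its reference, so
such a floor silently reduces the correction to the identity.)

The synthetic generator embeds the *forward* constant-offset response
plus the atmospheric anomaly into simulated rings, so the default
correction chain inverts it exactly; this is a modelling convenience
for recovery testing, not evidence about real trees.

## Smoothing and compositing

Each dated, corrected series is smoothed with a 21-year Tukey biweight
mean: for each grid year, the robust location of all samples dated
within the decade before and after. The iteration starts at the window
median with the scale fixed at c·MAD/0.6745, c = 9; weights
(1 − u²)² vanish beyond |u| = 1, so a gross outlier contributes
nothing. A zero MAD (majority-identical window) returns the median.
Iterations stop at a relative tolerance of 1e-12 with a cap of 50 —
in practice convergence takes under ~25 iterations, so the estimator
is converged, not truncated. Windows with no samples produce no output
year: a growth hiatus leaves a gap rather than an interpolated bridge.

The composite is the per-year arithmetic mean of the smoothed trees
with standard error s/√k (k contributing trees; undefined for k = 1,
reported as NaN) and the tree count. The grid stays annual; "decadal"
resolution claims are carried by the smoothing, not by decimation.

## Statistics

**Mann-Kendall.** S = Σ_{i<j} sgn(x_j − x_i); the variance uses the
standard tie correction; Z applies a ±1 continuity correction and p is
the two-sided normal tail. At n = 8 the approximation agrees with exact
permutation enumeration to better than 0.01 (verified in the suite).
S is an integer and is reported as such, never rescaled.

**OLS trend.** Value-on-year least squares via scipy, with
F = (n−2)·R²/(1−R²) and the slope's two-sided p.

**Changepoints.** Mean-shift segmentation minimising
Σ segment SSE/σ̂² + β·(number of changepoints), with σ̂ a robust noise
scale from lag-1 differences (MAD/0.6745/√2). PELT prunes the exact
dynamic program without losing optimality (the SSE cost is
subadditive); binary segmentation is retained as the greedy
cross-check. Penalties: BIC-style β = 2·log n, MBIC-style β = 3·log n
(the constant-penalty form of the modified BIC; the full form adds
segment-length terms), or a manual β. Change years are the first year
of each new segment. On heavily smoothed series the lag-1-difference
noise estimate is very small, so changepoints proliferate; for
composites a minimum segment length (e.g. 5 years) and the MBIC
penalty are the sensible defaults, and segment means always equal the
per-segment arithmetic means by construction.

**Forcing correlations.** Composite and index are aligned on common
integer years, optionally windowed and smoothed identically (centered
moving average) before Pearson r. The p-values carry *no*
autocorrelation correction — matching common practice in proxy
comparison tables — so every result also reports the lag-1
autocorrelation of both smoothed sides; after 10-year smoothing these
approach 1 and nominal p-values are optimistic by an order of
magnitude or more. The suite demonstrates the inflation directly
(independent AR(1) pairs reject at well above the nominal 5%).

## The synthetic world

Defaults emulate a four-core, ~700-year semi-arid study:

| quantity | default | why |
|---|---|---|
| span | 1300–2015 CE | ~700-year living-tree archive |
| rainfall mean | 450 mm/yr | semi-arid margin |
| rainfall trend | −15 mm/century | slow drying |
| centennial cycle | 60 mm amplitude, 200-yr period, mean-centred | wet/dry phases of a few generations |
| interannual noise | AR(1), φ = 0.6, sd 40 mm | red year-to-year variability |
| δ13C baseline | −25.3‰ | C3 wood cellulose |
| rainfall sensitivity | −0.35‰ per 100 mm | negative proxy response |
| signal + measurement noise | 0.15‰ + 0.10‰ | below a 0.2‰ replication error |
| growth rates | 0.61–0.99 samples/yr | 430–710 samples per core |
| hiatus (one core) | 1500–1700 CE | multi-century growth stop |
| dates per core | 12–15, σ_lab 25 14C yr | typical AMS campaign |
| curve wiggle | 20 14C yr amplitude, 150-yr period | 1σ intervals a few decades wide |
| atmosphere | δ13C −6.3‰ → −8.3‰, CO2 280 → 400 ppm, flat before 1850, quadratic ramp after | Suess-era shape |

All randomness flows from one seed through deterministically spawned
child seeds: identical seeds regenerate bit-identical worlds, and
different seeds change only noise realisations, never structure (core
lengths, tie points, hiatus placement).

What the generator does **not** emulate: variable growth rates within a
core (growth is exactly linear between hiatus boundaries, so the
tie-point model class is correctly specified by construction), juvenile
isotope effects, between-tree response differences, laboratory drift,
reservoir effects, or any mechanistic stomatal physiology. Passing
recovery tests therefore shows the *pipeline* is faithful — not that
real chronologies are free of the age-model structural error these
idealisations remove.

## Recovery results the suite enforces

With the defaults above, across 50 seeded replicates: the composite
correlates with the hidden annual rainfall at r ≤ −0.7, and the
Mann-Kendall test recovers the injected drying sign at p < 0.05, each
in ≥ 90% of replicates. HPD intervals cover the true year in 64–72% of
500 simulated dates. A 0.5‰ mean step at 1600 CE injected into all
four trees (0.15‰ noise) is located within ±10 years in ≥ 90% of
replicates. Exact tie points recover true ages to floating-point
accuracy; anchors jittered by ±5 years bound the mean absolute age
error by 5 years.

## Known limitations

- Tie points carry no uncertainty, so neither do assigned ages; the
  composite's standard errors reflect between-tree spread only.
- The pin correction endpoints bracket but do not estimate the plant's
  CO2 response; results after ~1900 should be read with the spread of
  the two modes in mind (with the default records the offset endpoint
  reaches ~4‰ by 2015, an upper bound by design).
- Correlation p-values ignore serial dependence (reported lag-1
  autocorrelations are the guard rail).
- The MBIC penalty is the constant approximation; segmentations of
  very smooth series remain penalty-sensitive.
- Calibration assumes Gaussian lab errors and a Gaussian curve
  uncertainty; no reservoir or fractionation corrections are applied.
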