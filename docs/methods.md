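# Methods

This note documents the models, numerical choices and validation design
behind `phenopop`, in the order the pipeline runs them.

## Seasonal NDVI model and growing-season metrics

Each pixel-year NDVI series (23 sixteen-day composites, midpoints at DOY
8, 24, ..., 360 on a fixed 365-day calendar) is modelled with the
six-parameter double-logistic curve

    ndvi(t) = b + A * ( 1/(1 + e^{-r_1 (t - m_1)}) + 1/(1 + e^{r_2 (t - m_2)}) - 1 )

with baseline `b` (winter NDVI), amplitude `A`, rise/fall midpoints
`m_1 < m_2` (days) and rates `r_1, r_2` (1/day).  Parameters are
estimated by bounded nonlinear least squares (trust-region reflective),
initialized from the data: `b` at the 10th percentile, `A` at the range,
midpoints at the half-range crossings, rates at 0.1/day.  The bounds
(midpoints inside the year, rates in [1e-3, 2]) prevent the rise and
fall sigmoids from swapping roles.  Series whose range falls below a
configurable amplitude floor (default 0.05 NDVI) are rejected as having
no seasonal signal, and non-converged fits are flagged and refused by
the metric extractor.

From a fitted curve, evaluated on a daily grid (DOY 1-365):

- **SOS / EOS** — first upcrossing before the peak / first downcrossing
  after the peak of `b + 0.25 A`, located by linear interpolation
  between grid days, so both are real-valued days.  The 25% threshold is
  configurable.  Because the fitted curve is unimodal by construction
  the crossings are unique.
- **DOP** — the grid argmax refined by a parabolic step through the
  three surrounding grid values.
- **LOS** — computed literally as `EOS - SOS`, so the identity holds to
  the last bit for every record.
- **Productivity** — the trapezoidal integral of the absolute fitted
  curve over `[SOS, EOS]` on the daily grid, with the two real-valued
  endpoints included exactly.  This differs from snapping the endpoints
  to whole days by well under 0.1% and removes a quantization artifact
  when comparing against finer quadrature.

Per-pixel metrics are averaged (unweighted) over valid pixels to
stratum-year values; covariates are then z-scored within stratum using
the sample SD (n-1), with the means/SDs retained.  Collinearity is
summarized by the mean across strata of within-stratum Pearson
correlations, skipping strata with under three shared years or constant
series.

A known limitation: when the seasonal curve has a broad plateau, DOP is
intrinsically ill-determined under composite noise — at noise SD 0.02
the fitted peak can move several days between noise draws even though
SOS and EOS stay within about 3 days.  This mirrors the behaviour of
peak-date estimates on real NDVI composites.

## Spring snow cover duration

Weekly stratum snow fractions are linearly interpolated to the daily
grid and summed over 1 February - 31 July (DOY 32-212, 181 days;
non-leap calendar throughout).  Fractional-day accounting is used
rather than a binary threshold: it agrees with day counting when
fractions are 0/1 and is continuous in the inputs, which makes the
monotonicity of SSCD in the melt date exactly testable.  Grid-cell
values are aggregated to strata by overlap-area weighting.

## Population model

For one species, log population density `x_{t,i} = log(N_{t,i} / area_i)`
in stratum `i` and year `t` follows the hierarchical discrete Gompertz
model

    x_{t,i} = alpha + stratum_i + year_t + theta_i x_{t-1,i}
              + beta_1 c_{t-1,i} + beta_lat c_{t-1,i} (lat_i - min lat)
              + eps_{t,i}

with crossed random intercepts `stratum_i ~ N(0, s_stratum^2)` and
`year_t ~ N(0, s_year^2)`, a stratum-varying density-dependence slope
`theta_i ~ N(theta, s_theta^2)`, and residuals `eps_{t,i} ~ N(0, s_i^2)`
with one variance per stratum.  The growing-season covariate `c` enters
with lag 1, standardized within stratum; latitude is coded as
`lat_i - min(lat_i)` so the main effect is the effect at the
southernmost stratum and a positive interaction means a stronger effect
farther north.  Length-of-season models carry SOS as an extra nuisance
covariate, reflecting `LOS = EOS - SOS`.  Records with zero abundance
are dropped (log undefined) from both response and lag positions, with
the count logged; the stratum inclusion filter (below) makes this rare.

### REML estimation

Variance parameters are estimated by restricted maximum likelihood on
the log-SD scale.  Writing the marginal covariance as
`V = R + Z D Z'` (R diagonal by stratum, D diagonal with one variance
per random-effect column), the restricted deviance

    -2 l_R = log|V| + log|X' V^-1 X| + r' V^-1 r + (n - p) log 2pi

is evaluated through the Woodbury identity: with per-stratum Gram
matrices of `[Z X y]` precomputed once, each evaluation costs
O(q^3 + m q^2) for q random-effect columns instead of O(n^3).  The
analytic gradient (trace and quadratic forms against `P = V^-1 -
V^-1 X (X'V^-1X)^-1 X'V^-1`) is supplied to L-BFGS-B; both the
likelihood and the gradient are verified in the test suite against a
from-definition dense implementation and finite differences.

Numerical choices:

- log-SDs bounded in [-10, 4]; three deterministic starts derived from
  the OLS residual SD (component/residual scale factors 0.5/1, 0.1/1,
  1/0.5) guard against local optima; the best successful start wins,
  and a start that ends with an "abnormal" line-search exit still
  counts as converged when its KKT projected gradient is below 1e-3.
- fitted SDs below 1e-4 are reported as exact zeros with a boundary
  flag; variance components are not inferential targets and no
  boundary-corrected test is attempted for them.
- fixed effects are recovered by GLS at the optimum with covariance
  `(X' V^-1 X)^-1`; Wald tests use the standard normal reference
  (two-sided), CIs are `estimate ± z_{0.975} SE`.  The normal (rather
  than a t) reference is pinned for reproducibility; at panel sizes of
  hundreds of observations the difference is negligible for 5%-level
  decisions, though it does understate extreme-tail p-values (see the
  battery validation below).

## Test battery and decisions

Per species and covariate (SOS, DOP, LOS, productivity) one model with
main effect + latitude interaction is fitted; each contributes two
hypothesis tests, so eight species give a pool of 64.  The SOS nuisance
term inside LOS models is a control and never enters the pool.
Benjamini-Hochberg q-values are computed over the pooled unadjusted
p-values (step-up, hand-implemented and cross-checked against both a
brute-force step-up and statsmodels); non-converged fits shrink the
pool, and the pool size actually used is recorded in run metadata.  An
effect is "supported" when any associated term has q < 0.05; it is
interpreted relative to latitude when the interaction's unadjusted
p < 0.05, otherwise the main term is read at the baseline (southernmost)
latitude.  Both thresholds are configurable.

The stratum inclusion rule retains a species-stratum only when the
species was recorded (abundance > 0) in strictly more than five years
of its series, so presence in exactly five years is excluded.

## Synthetic-data generator

The generator is first-class, tested code; it is the ground truth every
downstream stage is validated against.

- **NDVI** — double-logistic curves per stratum-year plus i.i.d.
  Gaussian composite noise (default SD 0.02 NDVI, a typical
  post-compositing residual level).  Spring timing shifts 1.5 days later
  per degree north, with a shared interannual anomaly (SD 6 days), a
  stratum-year jitter (SD 3 days) and ~8% interannual amplitude
  variation — enough structure to give the standardized covariates
  realistic within-stratum variance.
- **Snow** — fraction 1 before, 0 after a linear 28-day melt ramp
  centred 10 days before the NDVI rise midpoint.  Tying melt to the
  same latent spring timing makes the positive SSCD-SOS association a
  construction, not an accident, which the pipeline then recovers.
- **Ducks** — the Gompertz recursion iterated forward with all random
  draws from one seeded generator; per-stratum substreams are derived
  from the seed and stratum index so results are independent of
  iteration order.  Default truth: alpha = 1.0, theta = 0.5 (stationary
  log density 2.0), s_stratum = s_year = 0.1, s_theta = 0.05, residual
  SD 0.2 — fluctuation magnitudes in line with survey-scale abundance
  series.  Abundance is `exp(x) * area`, rounded only on export.  An
  optional lognormal observation error is available but validation
  targets use the process-only model, matching the fitted (conditional)
  model.

What the generator does *not* emulate: spatial autocorrelation among
pixels, snow/cloud contamination of composites, survey observation
error in the default truth, and species interactions.  Passing tests
therefore demonstrate the correctness and calibration of the
estimation machinery under the stated model, not robustness to those
real-data complications.

## Validation design

All validation experiments are seeded library functions
(`phenopop.validation`):

- **Recovery** — 12 strata x 38 years, covariate effect -0.06 with the
  default variance components, 200 replicates: mean estimate within
  0.01 of truth and empirical 95% CI coverage inside [0.90, 0.98].
- **Type-I error** — same design with a null effect, 2000 replicates:
  Wald rejection at the 5% level stays within [0.03, 0.075].  The rate
  sits near 0.06-0.07, the expected mild anticonservatism of Wald
  inference that ignores variance-component uncertainty.
- **Null batteries** — 20 replicate end-to-end pipelines (8 species,
  8 strata x 20 years, 1 pixel per stratum, all effects zero): the
  share of BH-supported tests stays below the nominal 5% (observed well
  under 1%).  The per-battery frequency of *any* discovery runs above
  5% because the z reference understates extreme-tail p-values — the
  pool's smallest p-values are exactly where the z-vs-t difference is
  largest.  This is a documented consequence of the pinned z reference,
  visible in the reported numbers.

Problem sizes for these experiments (replicate counts, strata, years,
pixel counts) are the package's chosen validation design: large enough
that Monte-Carlo error is small against every band checked, small
enough that the full suite reruns in minutes.
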