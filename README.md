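# phenopop

Do warmer, earlier or more productive growing seasons change how fast
boreal duck populations grow?  `phenopop` implements the full analysis
pipeline for that question: it extracts growing-season metrics from
satellite NDVI time series, summarizes spring snow-cover duration, and
links both to annual population growth of breeding ducks through
hierarchical discrete Gompertz models with false-discovery-rate control
over the resulting battery of hypothesis tests.  A ground-truth
synthetic-data generator stands in for the satellite and aerial-survey
downloads, so every stage of the pipeline is testable end to end
against known parameters.

It is aimed at population ecologists and biostatisticians who want a
reproducible, fully seeded version of this analysis pattern: seasonal
curve fitting → covariate construction → mixed-model battery → decision
table.

## The models

**Phenology.**  Each pixel-year series of 16-day NDVI composites is fit
with a six-parameter double-logistic curve
`b + A(sigmoid_rise + sigmoid_fall − 1)`.  From the fitted curve we
extract start of season (SOS, first upcrossing of `b + 0.25A`), date of
peak (DOP), end of season (EOS, first downcrossing after the peak),
length of season (LOS = EOS − SOS) and productivity (area under the
curve from SOS to EOS).  Metrics are averaged to stratum-years and
z-scored within stratum.

**Population growth.**  For each species, log population density
follows the hierarchical discrete Gompertz model

    x_{t,i} = α + stratum_i + year_t + θ_i x_{t−1,i}
              + β₁ c_{t−1,i} + β_lat c_{t−1,i} (lat_i − min lat) + ε_{t,i}

    stratum_i ~ N(0, σ²_stratum)    year_t ~ N(0, σ²_year)
    θ_i ~ N(θ, σ²_θ)                ε_{t,i} ~ N(0, σ²_i)

with crossed stratum/year random intercepts, a random
density-dependence slope, stratum-specific residual variances, and the
growing-season covariate `c` entering with lag 1.  Estimation is REML;
fixed effects get z-based Wald tests.  Each species × covariate model
contributes a main effect and a latitude interaction to one
Benjamini–Hochberg pool (64 tests for 8 species × 4 covariates);
effects with q < 0.05 are called supported, and interactions with
unadjusted p < 0.05 are interpreted as latitude-dependent.

## Worked example

Simulate two species over 6 strata × 20 years — one (mallard) whose
growth is truly driven by spring timing (β = −0.25 on the standardized
covariate), one (scaup) with no effect — then run the full analysis:

```python
from phenopop import RunConfig
from phenopop.config import DuckConfig, SeasonConfig, default_strata
from phenopop.pipeline import run_analysis, simulate_inputs

cfg = RunConfig(seed=42, years=(2000, 2019),
                species={"mallard": (2000, 2019), "scaup": (2000, 2019)},
                strata=default_strata(6, n_pixels=2),
                season=SeasonConfig(noise_sd=0.02),
                duck=DuckConfig(per_species={"mallard": {"beta_main": -0.25}}))
res = run_analysis(simulate_inputs(cfg), cfg)
print(res["decision_table"][["species", "covariate", "supported", "conclusion"]])
```

The decision table recovers exactly the planted structure — the
mallard–SOS effect and nothing else:

```
species    covariate  supported                           conclusion
mallard          dop      False                   no effect detected
mallard          los      False                   no effect detected
mallard productivity      False                   no effect detected
mallard          sos       True negative effect at baseline latitude
  scaup          dop      False                   no effect detected
  scaup          los      False                   no effect detected
  scaup productivity      False                   no effect detected
  scaup          sos      False                   no effect detected
```

and the correlation report shows the expected covariate structure
(earlier springs ↔ longer, more productive seasons; snow-cover duration
tracking SOS): `r̄(sos, los) = −0.87`, `r̄(los, productivity) = 0.87`,
`r̄(sscd, sos) = 0.99` on this synthetic scenario.

A single fitted model is a statsmodels-style object:

```python
from phenopop import GompertzModel, ModelSpec
model = GompertzModel.from_panel(panel, covariates, ModelSpec("sos"))
print(model.fit().summary())
```

```
Hierarchical Gompertz growth model (REML)
================================================================
Observations: 114   Strata: 6   Years: 19
Restricted log-likelihood: -4.1771   Converged: True
----------------------------------------------------------------
term                  coef        se       z    P>|z|    [0.025    0.975]
const               1.2017    0.1844    6.52    0.000    0.8402    1.5632
x_lag               0.4634    0.0721    6.43    0.000    0.3221    0.6047
sos                -0.1722    0.0467   -3.69    0.000   -0.2637   -0.0807
sos:lat            -0.0059    0.0041   -1.44    0.149   -0.0138    0.0021
----------------------------------------------------------------
sigma_stratum 0.1931   sigma_year 0.1710   sigma_theta 0.0000
sigma_resid by stratum: s01=0.2178, s02=0.1757, ...
```

Here `x_lag` is the mean density-dependence slope θ (values below one
mean density-dependent growth), `sos` the covariate effect at the
southernmost stratum, and `sos:lat` its change per degree of latitude.

The same pipeline is available from the shell:

```sh
phenopop all --seed 42 --config run.yaml --out run/
```

which writes the simulated inputs and the analysis outputs.  All files
are tidy CSV: `ndvi.csv` (stratum_id, pixel_id, year, doy, ndvi),
`snow.csv` (stratum_id, year, doy, snow_frac), `ducks.csv` (species,
stratum_id, year, x, abundance, latitude, area), `season_metrics.csv`
(stratum_id, year, sos, dop, eos, los, productivity, n_pixels_valid),
`sscd.csv` (stratum_id, year, sscd), plus `correlations.csv`,
`battery_results.csv` (one row per hypothesis test with estimate, SE,
CI, p, BH q), `decision_table.csv` and JSON metadata
(`truth.json`, `input_hashes.json`, `run_metadata.json`) carrying the
generating parameters, seeds, file hashes and the BH pool size used.
Individual stages are available as `phenopop simulate | phenology |
snow | fit | battery | report`.

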