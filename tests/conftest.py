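import numpy as np
import pandas as pd
import pytest

from phenopop import CovariatePanel, SeasonTruth, StratumSpec, SyntheticTruth


@pytest.fixture
def strata3():
    return [StratumSpec("s01", 54.0, 30000.0, n_pixels=2),
            StratumSpec("s02", 58.0, 40000.0, n_pixels=2),
            StratumSpec("s03", 62.0, 50000.0, n_pixels=2)]


@pytest.fixture
def season_truth():
    # the well-separated reference season used across phenology tests
    return SeasonTruth(baseline=0.2, amplitude=0.5, rise_midpoint=120.0,
                       rise_rate=0.15, fall_midpoint=260.0, fall_rate=0.12,
                       noise_sd=0.0)


def make_standardized_covariate(strata, years, seed):
    """Per-stratum z-scored i.i.d. normal covariate panel."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in strata:
        v = rng.normal(size=len(years))
        v = (v - v.mean()) / v.std(ddof=1)
        rows += [{"stratum_id": s.stratum_id, "year": y, "value": vv}
                 for y, vv in zip(years, v)]
    return CovariatePanel(name="cov", data=pd.DataFrame(rows), standardized=True)


def simulate_fitted_panel(strata, years, seed, beta=0.0, **truth_kwargs):
    """Simulated duck panel plus the covariate that (optionally) drives it."""
    from phenopop import simulate_duck_panel
    cov = make_standardized_covariate(strata, years, seed=seed + 500_000)
    defaults = dict(alpha=1.0, theta_mean=0.5, sigma_theta=0.05,
                    sigma_stratum=0.1, sigma_year=0.1, sigma_resid=0.2)
    defaults.update(truth_kwargs)
    truth = SyntheticTruth(beta_main=beta, seed=seed, **defaults)
    panel = simulate_duck_panel(strata, truth, cov.data, years)
    return panel, cov, truth


@pytest.fixture
def strata12():
    return [StratumSpec(f"s{i:02d}", 54.0 + i, 30000.0 + 1000.0 * i)
            for i in range(12)]
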