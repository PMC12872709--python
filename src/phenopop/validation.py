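"""Simulation-based validation experiments for the Gompertz pipeline.

These are the package's own calibration checks: parameter recovery and
confidence-interval coverage under a known truth, type-I error of the
Wald test under a null effect, and the false-discovery behaviour of
replicate end-to-end test batteries under a global null.  They exist as
library functions so that validation runs are reproducible from a single
seed and usable both from tests and from reporting scripts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DuckConfig, RunConfig, SeasonConfig, default_strata
from .gompertz import GompertzModel, ModelSpec
from .phenology import CovariatePanel
from .pipeline import run_analysis, simulate_inputs
from .synth import StratumSpec, SyntheticTruth, simulate_duck_panel

#: generating truth of the recovery/type-I study design
RECOVERY_TRUTH = dict(alpha=1.0, theta_mean=0.5, sigma_theta=0.05,
                      sigma_stratum=0.1, sigma_year=0.1, sigma_resid=0.2)
RECOVERY_BETA = -0.06


def _design_strata(n_strata: int) -> list[StratumSpec]:
    return [StratumSpec(f"s{i:02d}", 54.0 + i, 30000.0) for i in range(n_strata)]


def _standardized_covariate(strata, years, rng) -> CovariatePanel:
    rows = []
    for s in strata:
        v = rng.normal(size=len(years))
        v = (v - v.mean()) / v.std(ddof=1)
        rows += [{"stratum_id": s.stratum_id, "year": y, "value": vv}
                 for y, vv in zip(years, v)]
    return CovariatePanel("cov", pd.DataFrame(rows), standardized=True)


def _one_wald(seed: int, beta: float, n_strata: int, n_years: int):
    strata = _design_strata(n_strata)
    years = list(range(1982, 1982 + n_years))
    rng = np.random.default_rng([seed, 17])
    cov = _standardized_covariate(strata, years, rng)
    truth = SyntheticTruth(beta_main=beta,
                           seed=int(rng.integers(2 ** 31)), **RECOVERY_TRUTH)
    panel = simulate_duck_panel(strata, truth, cov.data, years)
    model = GompertzModel.from_panel(
        panel, {"cov": cov},
        ModelSpec("cov", include_latitude_interaction=False))
    return model.fit().wald_test("cov")


def recovery_experiment(n_reps: int = 200, seed: int = 0,
                        beta: float = RECOVERY_BETA, n_strata: int = 12,
                        n_years: int = 38) -> dict:
    """Repeatedly simulate-and-refit; summarize bias and 95% CI coverage."""
    ests, covered = [], 0
    for r in range(n_reps):
        w = _one_wald((seed * 1_000_003 + r) % (2 ** 31), beta, n_strata,
                      n_years)
        ests.append(w.estimate)
        covered += int(w.ci_low <= beta <= w.ci_high)
    ests = np.asarray(ests)
    return {"n_reps": n_reps, "beta_truth": beta,
            "mean_estimate": float(ests.mean()),
            "abs_bias": float(abs(ests.mean() - beta)),
            "sd_estimate": float(ests.std(ddof=1)),
            "ci95_coverage": covered / n_reps}


def type1_experiment(n_reps: int = 500, seed: int = 0, n_strata: int = 12,
                     n_years: int = 38, alpha: float = 0.05) -> dict:
    """Wald rejection rate of the covariate main effect under beta = 0."""
    rej = 0
    for r in range(n_reps):
        w = _one_wald((seed * 2_000_029 + 10_000_000 + r) % (2 ** 31), 0.0,
                      n_strata, n_years)
        rej += int(w.p < alpha)
    return {"n_reps": n_reps, "alpha": alpha, "rejection_rate": rej / n_reps}


def _null_battery_config(seed: int, n_strata: int, years: tuple[int, int],
                         n_species: int = 8) -> RunConfig:
    species = {name: years for name in list(RunConfig().species)[:n_species]}
    return RunConfig(seed=seed, years=years, species=species,
                     strata=default_strata(n_strata, n_pixels=1),
                     season=SeasonConfig(noise_sd=0.02),
                     duck=DuckConfig(beta_main=0.0, beta_lat=0.0))


def null_battery_experiment(n_batteries: int = 20, seed: int = 0,
                            n_strata: int = 8,
                            years: tuple[int, int] = (2000, 2019)) -> dict:
    """Run replicate end-to-end batteries with no true covariate effects.

    Under the global null every BH discovery is false, so the share of
    batteries with at least one supported test estimates the FDR, which
    the step-up procedure bounds by the nominal level.
    """
    any_disc, n_tests, total_disc = 0, [], 0
    for b in range(n_batteries):
        cfg = _null_battery_config((seed * 3_000_017 + b) % (2 ** 31),
                                   n_strata, years)
        res = run_analysis(simulate_inputs(cfg), cfg)
        supported = int(res["battery_results"]["supported"].sum())
        any_disc += int(supported > 0)
        total_disc += supported
        n_tests.append(res["metadata"]["n_tests"])
    return {"n_batteries": n_batteries,
            "tests_per_battery": n_tests,
            "any_discovery_rate": any_disc / n_batteries,
            "total_discoveries": total_disc}
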