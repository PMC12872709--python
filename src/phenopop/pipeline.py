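"""End-to-end pipeline: simulate inputs, extract phenology, fit the battery.

The scenario builder turns a :class:`~phenopop.config.RunConfig` into
per-stratum-year generating truths: seasonal NDVI curves whose spring
timing shifts with latitude and fluctuates between years, snow melt days
tied to that same timing (so snow-cover duration and SOS are positively
associated by construction), and duck panels driven by the latent spring
timing through the Gompertz recursion.  All randomness flows from the
run seed through named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import inference, phenology, snow, synth
from .config import RunConfig
from .gompertz import log_density_panel
from .inference import BatteryConfig
from .phenology import CovariatePanel

logger = logging.getLogger(__name__)


@dataclass
class Scenario:
    """Everything the generators need, derived from one config + seed."""

    config: RunConfig
    season_truths: dict        # stratum -> year -> SeasonTruth
    melt_days: dict            # stratum -> year -> day of year
    driver: CovariatePanel     # standardized latent spring timing
    duck_truths: dict          # species -> SyntheticTruth


def _substream(seed: int, tag: str) -> np.random.Generator:
    h = int.from_bytes(hashlib.sha256(tag.encode()).digest()[:4], "big")
    return np.random.default_rng([seed, h])


def build_scenario(cfg: RunConfig, seed: int | None = None) -> Scenario:
    """Draw the stratum-year seasonal truths and species model truths."""
    seed = cfg.seed if seed is None else seed
    sc = cfg.season
    years = cfg.year_list
    rng = _substream(seed, "scenario")
    lat0 = min(s.latitude for s in cfg.strata)

    year_anom = rng.normal(0.0, sc.interannual_sd, size=len(years))
    fall_anom = rng.normal(0.0, sc.fall_interannual_sd, size=len(years))
    truths, melt_days = {}, {}
    rise_rows = []
    for s in cfg.strata:
        jit = rng.normal(0.0, sc.stratum_year_sd, size=len(years))
        amp = sc.amplitude * (1.0 + rng.normal(0.0, sc.amplitude_cv,
                                               size=len(years)))
        truths[s.stratum_id] = {}
        melt_days[s.stratum_id] = {}
        for k, year in enumerate(years):
            rise = (sc.rise_midpoint + sc.lat_day_shift * (s.latitude - lat0)
                    + year_anom[k] + jit[k])
            fall = sc.fall_midpoint + fall_anom[k]
            truths[s.stratum_id][year] = synth.SeasonTruth(
                baseline=sc.baseline, amplitude=float(max(amp[k], 0.05)),
                rise_midpoint=float(rise), rise_rate=sc.rise_rate,
                fall_midpoint=float(max(fall, rise + 30.0)),
                fall_rate=sc.fall_rate, noise_sd=sc.noise_sd)
            melt_days[s.stratum_id][year] = float(rise - cfg.snow.melt_offset)
            rise_rows.append({"stratum_id": s.stratum_id, "year": year,
                              "value": rise})
    driver = phenology.standardize_by_stratum(
        CovariatePanel(name="spring_timing", data=pd.DataFrame(rise_rows)))

    duck_truths = {}
    for si, species in enumerate(cfg.species):
        over = cfg.duck.per_species.get(species, {})
        duck_truths[species] = synth.SyntheticTruth(
            alpha=over.get("alpha", cfg.duck.alpha),
            theta_mean=over.get("theta_mean", cfg.duck.theta_mean),
            sigma_theta=over.get("sigma_theta", cfg.duck.sigma_theta),
            sigma_stratum=over.get("sigma_stratum", cfg.duck.sigma_stratum),
            sigma_year=over.get("sigma_year", cfg.duck.sigma_year),
            sigma_resid=over.get("sigma_resid", cfg.duck.sigma_resid),
            beta_main=over.get("beta_main", cfg.duck.beta_main),
            beta_lat=over.get("beta_lat", cfg.duck.beta_lat),
            obs_sd=over.get("obs_sd", cfg.duck.obs_sd),
            seed=int(_substream(seed, f"ducks/{species}").integers(2 ** 31)))
    return Scenario(config=cfg, season_truths=truths, melt_days=melt_days,
                    driver=driver, duck_truths=duck_truths)


def simulate_inputs(cfg: RunConfig, seed: int | None = None) -> dict:
    """Generate the full synthetic input set as tidy DataFrames."""
    seed = cfg.seed if seed is None else seed
    scen = build_scenario(cfg, seed)
    ndvi = synth.generate_ndvi_panel(
        cfg.strata, scen.season_truths, cfg.year_list,
        seed=int(_substream(seed, "ndvi").integers(2 ** 31)))
    snow_panel = synth.generate_snow_panel(
        cfg.strata, scen.melt_days, cfg.year_list,
        melt_window=cfg.snow.melt_window)
    ducks = []
    for species in cfg.species:
        panel = synth.simulate_duck_panel(
            cfg.strata, scen.duck_truths[species], scen.driver.data,
            cfg.species_years(species), x0=cfg.duck.x0)
        panel.insert(0, "species", species)
        ducks.append(panel)
    return {"scenario": scen, "ndvi": ndvi, "snow": snow_panel,
            "ducks": pd.concat(ducks, ignore_index=True)}


def phenology_stage(ndvi: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Per-pixel curve fits -> stratum-year season metrics table."""
    th = cfg.thresholds
    pixel = phenology.pixel_metrics_table(
        ndvi, amplitude_floor=th.amplitude_floor, threshold=th.season_threshold)
    return phenology.stratum_annual_average(pixel)


def snow_stage(snow_panel: pd.DataFrame) -> pd.DataFrame:
    return snow.compute_sscd(snow_panel)


def covariate_stage(metrics: pd.DataFrame) -> dict[str, CovariatePanel]:
    """Standardized covariate panels for the model battery."""
    out = {}
    for name in ("sos", "dop", "los", "productivity"):
        panel = CovariatePanel.from_metrics(metrics, name)
        out[name] = phenology.standardize_by_stratum(panel)
    return out


def correlation_report(covariates: dict[str, CovariatePanel],
                       sscd: pd.DataFrame) -> pd.DataFrame:
    """Mean pairwise correlations among covariates and with SSCD."""
    summaries = phenology.mean_pairwise_correlation(list(covariates.values()))
    for name in ("sos", "dop"):
        if name in covariates:
            summaries.append(
                snow.sscd_phenology_correlation(sscd, covariates[name]))
    return pd.DataFrame([
        {"var_a": s.pair[0], "var_b": s.pair[1], "mean_r": s.mean_r,
         "n_strata_used": s.n_strata_used,
         "n_strata_skipped": s.n_strata_skipped}
        for s in summaries])


def run_analysis(data: dict, cfg: RunConfig) -> dict:
    """Phenology -> snow -> standardization -> battery -> decisions."""
    th = cfg.thresholds
    metrics = phenology_stage(data["ndvi"], cfg)
    sscd = snow_stage(data["snow"])
    covariates = covariate_stage(metrics)
    correlations = correlation_report(covariates, sscd)

    panels = {}
    for species, grp in data["ducks"].groupby("species", sort=False):
        panels[species] = log_density_panel(grp.drop(columns="species"))
    bcfg = BatteryConfig(q_threshold=th.q_threshold,
                         interaction_gate=th.interaction_gate,
                         min_recorded=th.min_recorded)
    results, metadata = inference.run_battery(panels, covariates, bcfg)
    decisions = inference.decision_table(results, q_threshold=th.q_threshold,
                                         interaction_gate=th.interaction_gate)
    return {"season_metrics": metrics, "sscd": sscd,
            "correlations": correlations, "battery_results": results,
            "decision_table": decisions, "metadata": metadata,
            "covariates": covariates}


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
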