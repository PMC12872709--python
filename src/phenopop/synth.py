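"""Synthetic inputs with known ground truth.

Three generators emulate the raw inputs of the analysis: 16-day NDVI
composites per stratum pixel (double-logistic seasonal shape plus i.i.d.
Gaussian noise), weekly stratum snow fractions crossing from 1 to 0
across a spring melt window, and species x stratum x year duck abundance
panels produced by iterating the hierarchical discrete Gompertz model

    x_{t,i} = alpha + stratum_i + year_t + theta_i * x_{t-1,i}
              + beta * covariate_{t-1,i} (+ beta_lat * covariate * latitude)
              + eps_{t,i}

forward in time, where x is log population density.  Every generator is
deterministic given its seed; per-stratum sub-streams are derived from
the seed and the stratum index so results do not depend on iteration
order.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenology import double_logistic

logger = logging.getLogger(__name__)

#: midpoints of the 16-day composite windows, DOY 8, 24, ..., 360
COMPOSITE_DOYS = np.arange(8.0, 361.0, 16.0)

#: weekly snow observation days, DOY 4, 11, ..., 361
WEEKLY_DOYS = np.arange(4.0, 362.0, 7.0)


class ConfigurationError(ValueError):
    """A generator was called with an incomplete or inconsistent setup."""


@dataclass(frozen=True)
class StratumSpec:
    """A survey stratum: its centroid latitude, area and pixel count."""

    stratum_id: str
    latitude: float  # degrees north
    area: float      # km^2
    n_pixels: int = 1

    def __post_init__(self):
        if not np.isfinite(self.latitude):
            raise ValueError(f"stratum {self.stratum_id}: latitude not finite")
        if self.area <= 0:
            raise ValueError(f"stratum {self.stratum_id}: area must be > 0")
        if self.n_pixels < 1:
            raise ValueError(f"stratum {self.stratum_id}: n_pixels must be >= 1")


@dataclass(frozen=True)
class SeasonTruth:
    """Generating parameters of one stratum-year seasonal NDVI curve."""

    baseline: float
    amplitude: float
    rise_midpoint: float
    rise_rate: float
    fall_midpoint: float
    fall_rate: float
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.rise_midpoint >= self.fall_midpoint:
            raise ValueError("rise_midpoint must precede fall_midpoint")
        if self.rise_rate <= 0 or self.fall_rate <= 0:
            raise ValueError("rates must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def curve_params(self) -> tuple[float, ...]:
        return (self.baseline, self.amplitude, self.rise_midpoint,
                self.rise_rate, self.fall_midpoint, self.fall_rate)

    def curve(self, t):
        return double_logistic(t, *self.curve_params)


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters of the Gompertz population model."""

    alpha: float = 1.0
    theta_mean: float = 0.5
    sigma_theta: float = 0.05
    sigma_stratum: float = 0.1
    sigma_year: float = 0.1
    sigma_resid: float | Mapping[str, float] = 0.2
    beta_main: float = 0.0
    beta_lat: float = 0.0
    obs_sd: float = 0.0  # optional lognormal observation error on abundance
    seed: int = 0

    def __post_init__(self):
        sds = [self.sigma_theta, self.sigma_stratum, self.sigma_year, self.obs_sd]
        if isinstance(self.sigma_resid, Mapping):
            sds += list(self.sigma_resid.values())
        else:
            sds.append(self.sigma_resid)
        if any(s < 0 for s in sds):
            raise ValueError("all standard deviations must be >= 0")

    def resid_sd(self, stratum_id: str) -> float:
        if isinstance(self.sigma_resid, Mapping):
            return float(self.sigma_resid[stratum_id])
        return float(self.sigma_resid)


def _stratum_rng(seed: int, index: int) -> np.random.Generator:
    # deterministic sub-stream per stratum, independent of iteration order
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(index + 1)[-1])


def generate_ndvi_panel(strata: list[StratumSpec],
                        truths: Mapping[str, Mapping[int, SeasonTruth]],
                        years, seed: int) -> pd.DataFrame:
    """Simulate 16-day NDVI composites for every stratum pixel and year.

    Returns a tidy frame with columns stratum_id, pixel_id, year, doy,
    ndvi: the double-logistic curve evaluated at the composite midpoint
    plus i.i.d. Gaussian noise.
    """
    years = list(years)
    if not years:
        raise ValueError("years must be non-empty")
    for s in strata:
        for year in years:
            try:
                truths[s.stratum_id][year]
            except KeyError:
                raise ConfigurationError(
                    f"missing SeasonTruth for stratum {s.stratum_id!r}, year {year}")

    frames = []
    for si, s in enumerate(strata):
        rng = _stratum_rng(seed, si)
        for year in years:
            truth = truths[s.stratum_id][year]
            clean = truth.curve(COMPOSITE_DOYS)
            noise = rng.normal(0.0, truth.noise_sd,
                               size=(s.n_pixels, COMPOSITE_DOYS.size))
            vals = clean[None, :] + noise
            frames.append(pd.DataFrame({
                "stratum_id": s.stratum_id,
                "pixel_id": np.repeat(np.arange(s.n_pixels), COMPOSITE_DOYS.size),
                "year": year,
                "doy": np.tile(COMPOSITE_DOYS, s.n_pixels),
                "ndvi": vals.ravel(),
            }))
    return pd.concat(frames, ignore_index=True)


def generate_snow_panel(strata: list[StratumSpec],
                        melt_day: Mapping[str, Mapping[int, float]],
                        years, melt_window: float = 28.0,
                        seed: int | None = None) -> pd.DataFrame:
    """Weekly stratum snow fractions: 1 before melt, 0 after, linear ramp.

    The ramp spans ``melt_window`` days centred on the stratum-year melt
    day.  The generator is deterministic (no weather noise); ``seed`` is
    accepted for interface symmetry and ignored.
    """
    years = list(years)
    rows = []
    for s in strata:
        for year in years:
            try:
                md = float(melt_day[s.stratum_id][year])
            except KeyError:
                raise ConfigurationError(
                    f"missing melt_day for stratum {s.stratum_id!r}, year {year}")
            if not (1.0 <= md <= 365.0):
                raise ValueError(f"melt_day {md} outside the calendar year")
            lo, hi = md - melt_window / 2.0, md + melt_window / 2.0
            if lo < 1.0 or hi > 365.0:
                raise ValueError(
                    f"melt window [{lo:.1f}, {hi:.1f}] exceeds the year")
            if melt_window == 0:
                frac = (WEEKLY_DOYS < md).astype(float)
            else:
                frac = np.clip((hi - WEEKLY_DOYS) / melt_window, 0.0, 1.0)
            rows.append(pd.DataFrame({
                "stratum_id": s.stratum_id, "year": year,
                "doy": WEEKLY_DOYS, "snow_frac": frac,
            }))
    return pd.concat(rows, ignore_index=True)


def simulate_duck_panel(strata: list[StratumSpec], truth: SyntheticTruth,
                        covariate: pd.DataFrame | None, years,
                        x0: float | Mapping[str, float] = 2.0) -> pd.DataFrame:
    """Iterate the Gompertz recursion forward to a stratum-year panel.

    Parameters
    ----------
    covariate : DataFrame or None
        Tidy stratum-year covariate (columns stratum_id, year, value); it
        enters the recursion with lag 1.  ``None`` means no covariate
        forcing (betas ignored).
    x0 : float or mapping
        Initial log density per stratum in the first year.

    Returns a frame with stratum_id, year, x (log density, birds/km^2),
    abundance (= exp(x) * area, unrounded), latitude and area.  With
    ``truth.obs_sd > 0`` a lognormal observation error multiplies the
    abundance but never feeds back into the dynamics.
    """
    years = sorted(years)
    rng = np.random.default_rng(truth.seed)
    m, T = len(strata), len(years)
    lat = np.array([s.latitude for s in strata])
    lat_std = lat - lat.min()

    cov = np.zeros((m, T))
    if covariate is not None and (truth.beta_main != 0 or truth.beta_lat != 0):
        wide = covariate.pivot(index="year", columns="stratum_id", values="value")
        missing = [(s.stratum_id, y) for s in strata for y in years[:-1]
                   if s.stratum_id not in wide.columns
                   or y not in wide.index or pd.isna(wide.at[y, s.stratum_id])]
        if missing:
            raise ConfigurationError(f"covariate missing for stratum-years: {missing[:5]}")
        for si, s in enumerate(strata):
            cov[si, :] = wide[s.stratum_id].reindex(years).to_numpy()

    b_strat = rng.normal(0.0, truth.sigma_stratum, size=m)
    u_year = rng.normal(0.0, truth.sigma_year, size=T)
    thetas = rng.normal(truth.theta_mean, truth.sigma_theta, size=m)
    resid_sd = np.array([truth.resid_sd(s.stratum_id) for s in strata])
    eps = rng.normal(0.0, 1.0, size=(m, T)) * resid_sd[:, None]

    x = np.empty((m, T))
    if isinstance(x0, Mapping):
        x[:, 0] = [float(x0[s.stratum_id]) for s in strata]
    else:
        x[:, 0] = float(x0)
    for t in range(1, T):
        x[:, t] = (truth.alpha + b_strat + u_year[t] + thetas * x[:, t - 1]
                   + truth.beta_main * cov[:, t - 1]
                   + truth.beta_lat * cov[:, t - 1] * lat_std
                   + eps[:, t])

    area = np.array([s.area for s in strata])
    abundance = np.exp(x) * area[:, None]
    if truth.obs_sd > 0:
        abundance = abundance * np.exp(rng.normal(0.0, truth.obs_sd, size=(m, T)))

    return pd.DataFrame({
        "stratum_id": np.repeat([s.stratum_id for s in strata], T),
        "year": np.tile(years, m),
        "x": x.ravel(),
        "abundance": abundance.ravel(),
        "latitude": np.repeat(lat, T),
        "area": np.repeat(area, T),
    })
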