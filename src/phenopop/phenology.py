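"""Double-logistic NDVI phenology: curve fitting and growing-season metrics.

Seasonal greenness in boreal landscapes follows a rise-plateau-fall shape
that is well captured by a six-parameter double-logistic curve,

    ndvi(t) = baseline + amplitude * (1 / (1 + exp(-rise_rate * (t - rise_midpoint)))
                                      + 1 / (1 + exp( fall_rate * (t - fall_midpoint)))
                                      - 1)

with t the day of year.  From a fitted curve we extract start of season
(SOS, first upcrossing of 25% of the seasonal amplitude), date of peak
(DOP), end of season (EOS, first downcrossing after the peak), length of
season (LOS = EOS - SOS) and productivity (the area under the curve
between SOS and EOS, in NDVI*days).  Per-pixel metrics are averaged to
stratum-year values, z-standardized within stratum, and summarized by
mean pairwise Pearson correlations across strata.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: daily evaluation grid (non-leap calendar throughout)
DAILY_GRID = np.arange(1.0, 366.0)

METRIC_COLUMNS = ["sos", "dop", "eos", "los", "productivity"]


class NoSeasonalAmplitudeError(ValueError):
    """Raised when a series has too little seasonal range to fit a curve."""


class SeasonUndefinedError(ValueError):
    """Raised when the 25%-amplitude crossings do not exist within the year."""


class ZeroVarianceError(ValueError):
    """Raised when a stratum series is constant and cannot be z-scored."""


def double_logistic(t, baseline, amplitude, rise_midpoint, rise_rate,
                    fall_midpoint, fall_rate):
    """Evaluate the double-logistic seasonal curve at days ``t``."""
    t = np.asarray(t, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-rise_rate * (t - rise_midpoint)))
    fall = 1.0 / (1.0 + np.exp(fall_rate * (t - fall_midpoint)))
    return baseline + amplitude * (rise + fall - 1.0)


@dataclass
class CurveFit:
    """Estimated double-logistic parameters for one pixel-year series."""

    baseline: float
    amplitude: float
    rise_midpoint: float
    rise_rate: float
    fall_midpoint: float
    fall_rate: float
    rss: float
    converged: bool

    @property
    def params(self) -> tuple[float, ...]:
        return (self.baseline, self.amplitude, self.rise_midpoint,
                self.rise_rate, self.fall_midpoint, self.fall_rate)

    def curve(self, t):
        return double_logistic(t, *self.params)


@dataclass
class SeasonMetrics:
    """Growing-season metrics extracted from one fitted curve.

    Days are real-valued: crossings are located by linear interpolation on
    the daily grid, and the peak by parabolic refinement around the grid
    argmax.
    """

    sos: float
    dop: float
    eos: float
    los: float
    productivity: float

    def __post_init__(self):
        if not (self.sos < self.dop < self.eos):
            raise SeasonUndefinedError(
                f"metrics out of order: sos={self.sos}, dop={self.dop}, eos={self.eos}")


def _half_crossing_init(doy, values):
    """Initial midpoints: days where the series crosses half its range."""
    half = 0.5 * (values.min() + values.max())
    above = values >= half
    rise = doy[len(doy) // 4]
    fall = doy[3 * len(doy) // 4]
    up = np.nonzero(~above[:-1] & above[1:])[0]
    down = np.nonzero(above[:-1] & ~above[1:])[0]
    if up.size:
        rise = 0.5 * (doy[up[0]] + doy[up[0] + 1])
    if down.size:
        fall = 0.5 * (doy[down[-1]] + doy[down[-1] + 1])
    if fall <= rise:
        rise, fall = doy[len(doy) // 4], doy[3 * len(doy) // 4]
    return rise, fall


def fit_double_logistic(doy, values, amplitude_floor: float = 0.05,
                        max_nfev: int = 2000) -> CurveFit:
    """Nonlinear least-squares fit of the double-logistic curve.

    Parameters
    ----------
    doy, values : array-like
        Composite days of year and NDVI values (>= 10 points spanning the
        year).
    amplitude_floor : float
        Minimum seasonal range; series flatter than this raise
        :class:`NoSeasonalAmplitudeError`.
    """
    doy = np.asarray(doy, dtype=float)
    values = np.asarray(values, dtype=float)
    if doy.size < 10:
        raise ValueError(f"need >= 10 composites, got {doy.size}")
    rng_val = values.max() - values.min()
    if rng_val < amplitude_floor:
        raise NoSeasonalAmplitudeError(
            f"seasonal range {rng_val:.4f} below amplitude floor {amplitude_floor}")

    base0 = np.percentile(values, 10)
    amp0 = rng_val
    rise0, fall0 = _half_crossing_init(doy, values)
    x0 = np.array([base0, amp0, rise0, 0.1, fall0, 0.1])
    lower = np.array([-0.5, amplitude_floor, 1.0, 1e-3, 1.0, 1e-3])
    upper = np.array([1.0, 2.0, 365.0, 2.0, 365.0, 2.0])
    x0 = np.clip(x0, lower + 1e-9, upper - 1e-9)

    def resid(p):
        return double_logistic(doy, *p) - values

    sol = least_squares(resid, x0, bounds=(lower, upper), max_nfev=max_nfev)
    base, amp, rise, rrate, fall, frate = sol.x
    converged = bool(sol.success) and rise < fall and amp >= 0
    return CurveFit(baseline=float(base), amplitude=float(amp),
                    rise_midpoint=float(rise), rise_rate=float(rrate),
                    fall_midpoint=float(fall), fall_rate=float(frate),
                    rss=float(2.0 * sol.cost), converged=converged)


def _cross_up(t, y, level, stop):
    """First upcrossing of ``level`` at index < stop, linearly interpolated."""
    for i in range(stop):
        if y[i] <= level < y[i + 1]:
            return t[i] + (level - y[i]) / (y[i + 1] - y[i]) * (t[i + 1] - t[i])
    return None


def _cross_down(t, y, level, start):
    for i in range(start, len(y) - 1):
        if y[i] >= level > y[i + 1]:
            return t[i] + (y[i] - level) / (y[i] - y[i + 1]) * (t[i + 1] - t[i])
    return None


def extract_season_metrics(fit: CurveFit, threshold: float = 0.25) -> SeasonMetrics:
    """Extract SOS/DOP/EOS/LOS/productivity from a converged curve fit.

    The fitted curve is evaluated on a daily grid (DOY 1-365).  SOS is the
    first rise through ``baseline + threshold*amplitude`` before the peak,
    EOS the first fall below it after the peak, and productivity the
    trapezoidal integral of the (absolute-valued) curve over [SOS, EOS].
    """
    if not fit.converged:
        raise ValueError("refusing to extract metrics from a non-converged fit")
    t = DAILY_GRID
    y = fit.curve(t)

    i_max = int(np.argmax(y))
    dop = t[i_max]
    if 0 < i_max < len(t) - 1:
        denom = y[i_max - 1] - 2.0 * y[i_max] + y[i_max + 1]
        if abs(denom) > 1e-12:
            dop = t[i_max] + 0.5 * (y[i_max - 1] - y[i_max + 1]) / denom

    level = fit.baseline + threshold * fit.amplitude
    sos = _cross_up(t, y, level, i_max)
    eos = _cross_down(t, y, level, i_max)
    if sos is None or eos is None:
        raise SeasonUndefinedError(
            f"no {threshold:.0%}-amplitude crossing within the year "
            f"(level={level:.3f})")

    # trapezoid on the daily grid, clipped to the real-valued season window
    interior = t[(t > sos) & (t < eos)]
    grid = np.concatenate([[sos], interior, [eos]])
    prod = float(np.trapezoid(np.abs(fit.curve(grid)), grid))
    return SeasonMetrics(sos=float(sos), dop=float(dop), eos=float(eos),
                         los=float(eos) - float(sos), productivity=prod)


def pixel_metrics_table(ndvi: pd.DataFrame, amplitude_floor: float = 0.05,
                        threshold: float = 0.25) -> pd.DataFrame:
    """Fit every pixel-year series in a tidy NDVI table and extract metrics.

    Input columns: stratum_id, pixel_id, year, doy, ndvi.  Output has one
    row per pixel-year with metric columns (NaN where the fit failed or the
    season was undefined) and a ``valid`` flag.
    """
    rows = []
    for (sid, pid, year), grp in ndvi.groupby(["stratum_id", "pixel_id", "year"],
                                              sort=True):
        rec = {"stratum_id": sid, "pixel_id": pid, "year": year,
               "valid": False}
        try:
            fit = fit_double_logistic(grp["doy"].to_numpy(),
                                      grp["ndvi"].to_numpy(),
                                      amplitude_floor=amplitude_floor)
            if fit.converged:
                m = extract_season_metrics(fit, threshold=threshold)
                rec.update(sos=m.sos, dop=m.dop, eos=m.eos, los=m.los,
                           productivity=m.productivity, valid=True)
        except (NoSeasonalAmplitudeError, SeasonUndefinedError) as exc:
            logger.warning("pixel %s/%s year %s: %s", sid, pid, year, exc)
        rows.append(rec)
    out = pd.DataFrame(rows)
    for col in METRIC_COLUMNS:
        if col not in out:
            out[col] = np.nan
    return out


def stratum_annual_average(pixel_metrics: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of per-pixel metrics over valid pixels per stratum-year.

    Returns one row per stratum-year with metric means and
    ``n_pixels_valid``; stratum-years with no valid pixel keep NaN metrics.
    """
    df = pixel_metrics.copy()
    if "valid" not in df:
        df["valid"] = df[METRIC_COLUMNS].notna().all(axis=1)
    df.loc[~df["valid"], METRIC_COLUMNS] = np.nan
    g = df.groupby(["stratum_id", "year"], sort=True)
    out = g[METRIC_COLUMNS].mean()
    out["n_pixels_valid"] = g["valid"].sum().astype(int)
    n_empty = int((out["n_pixels_valid"] == 0).sum())
    if n_empty:
        logger.warning("%d stratum-years have no valid pixel metrics", n_empty)
    return out.reset_index()


@dataclass
class CovariatePanel:
    """One covariate on a stratum-year grid, optionally z-scored by stratum."""

    name: str
    data: pd.DataFrame  # columns: stratum_id, year, value
    standardized: bool = False
    stats: pd.DataFrame | None = None  # per-stratum mean/sd used for scaling

    def __post_init__(self):
        required = {"stratum_id", "year", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"covariate panel missing columns {sorted(missing)}")

    @classmethod
    def from_metrics(cls, metrics: pd.DataFrame, name: str) -> "CovariatePanel":
        """Pull one metric column out of a stratum-year metrics table."""
        df = metrics[["stratum_id", "year", name]].rename(columns={name: "value"})
        return cls(name=name, data=df.dropna(subset=["value"]).reset_index(drop=True))

    def pivot(self) -> pd.DataFrame:
        return self.data.pivot(index="year", columns="stratum_id", values="value")


def standardize_by_stratum(panel: CovariatePanel) -> CovariatePanel:
    """Z-score a covariate within each stratum (sample SD, ddof=1).

    Requires >= 3 years per stratum and non-constant values; the stratum
    means/SDs used are retained on the returned panel.
    """
    df = panel.data.copy()
    stats = []
    for sid, grp in df.groupby("stratum_id", sort=True):
        v = grp["value"].to_numpy(dtype=float)
        if v.size < 3:
            raise ValueError(f"stratum {sid!r}: need >= 3 years, got {v.size}")
        mu, sd = v.mean(), v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ZeroVarianceError(f"stratum {sid!r}: constant series, SD is zero")
        df.loc[grp.index, "value"] = (v - mu) / sd
        stats.append({"stratum_id": sid, "mean": mu, "sd": sd})
    return replace(panel, data=df, standardized=True,
                   stats=pd.DataFrame(stats))


@dataclass
class CorrelationSummary:
    """Per-stratum Pearson correlations of a covariate pair and their mean."""

    pair: tuple[str, str]
    per_stratum_r: pd.Series
    mean_r: float
    n_strata_used: int
    n_strata_skipped: int = 0


def pair_correlation(a: CovariatePanel, b: CovariatePanel,
                      min_years: int = 3) -> CorrelationSummary:
    wa, wb = a.pivot(), b.pivot()
    strata = wa.columns.intersection(wb.columns)
    rs, skipped = {}, 0
    for sid in strata:
        joined = pd.concat([wa[sid], wb[sid]], axis=1, join="inner").dropna()
        if len(joined) < min_years:
            skipped += 1
            continue
        x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("pair (%s, %s): stratum %r constant, skipped",
                           a.name, b.name, sid)
            skipped += 1
            continue
        rs[sid] = float(np.corrcoef(x, y)[0, 1])
    per = pd.Series(rs, dtype=float)
    return CorrelationSummary(pair=(a.name, b.name), per_stratum_r=per,
                              mean_r=float(per.mean()) if len(per) else np.nan,
                              n_strata_used=len(per), n_strata_skipped=skipped)


def mean_pairwise_correlation(panels: list[CovariatePanel],
                              min_years: int = 3) -> list[CorrelationSummary]:
    """Mean across-strata Pearson r for every unordered pair of covariates.

    Within each stratum r is computed on the years shared by the pair;
    strata with < ``min_years`` shared years or a constant series are
    skipped (counted in the summary).
    """
    return [pair_correlation(a, b, min_years=min_years)
            for a, b in itertools.combinations(panels, 2)]
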