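"""Spring snow cover duration (SSCD) and its link to spring phenology.

SSCD is the number of snow-covered days in the second half of the snow
season, 1 February to 31 July (DOY 32-212 inclusive, 181 days on the
non-leap calendar used throughout).  Weekly snow fractions are linearly
interpolated to the daily grid and summed as fractional days, which
coincides with binary day counting when the fractions are 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenology import CorrelationSummary, CovariatePanel, pair_correlation

#: 1 February and 31 July as day-of-year, non-leap calendar
SEASON_START_DOY = 32
SEASON_END_DOY = 212
SEASON_DAYS = SEASON_END_DOY - SEASON_START_DOY + 1  # 181


@dataclass(frozen=True)
class SnowMetrics:
    stratum_id: str
    year: int
    sscd: float

    def __post_init__(self):
        if not (0.0 <= self.sscd <= SEASON_DAYS):
            raise ValueError(f"sscd {self.sscd} outside [0, {SEASON_DAYS}]")


def compute_sscd(weekly: pd.DataFrame) -> pd.DataFrame:
    """SSCD per stratum-year from weekly snow fractions.

    ``weekly`` columns: stratum_id, year, doy, snow_frac.  The weekly
    series must bracket the 1 Feb - 31 Jul window; fractions outside
    [0, 1] are rejected.  Returns a frame with stratum_id, year, sscd.
    """
    frac = weekly["snow_frac"].to_numpy(dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("snow fractions must lie in [0, 1]")
    days = np.arange(SEASON_START_DOY, SEASON_END_DOY + 1, dtype=float)
    rows = []
    for (sid, year), grp in weekly.groupby(["stratum_id", "year"], sort=True):
        grp = grp.sort_values("doy")
        doy = grp["doy"].to_numpy(dtype=float)
        if doy.min() > SEASON_START_DOY or doy.max() < SEASON_END_DOY:
            raise ValueError(
                f"stratum {sid!r} year {year}: weekly series must cover "
                f"DOY {SEASON_START_DOY}-{SEASON_END_DOY}")
        daily = np.interp(days, doy, grp["snow_frac"].to_numpy(dtype=float))
        rows.append(SnowMetrics(sid, int(year), float(daily.sum())))
    return pd.DataFrame([vars(r) for r in rows])


def area_weighted_sscd(cell_sscd: pd.DataFrame,
                       overlap: pd.DataFrame) -> pd.DataFrame:
    """Aggregate grid-cell SSCD to strata by overlap-area weighting.

    ``cell_sscd`` columns: cell_id, year, sscd; ``overlap`` columns:
    cell_id, stratum_id, area (weight proportional to the overlap of the
    cell with the stratum).  Weights must be nonnegative with at least
    one positive weight per stratum.
    """
    if (overlap["area"] < 0).any():
        raise ValueError("overlap areas must be >= 0")
    merged = cell_sscd.merge(overlap, on="cell_id")
    rows = []
    for (sid, year), grp in merged.groupby(["stratum_id", "year"], sort=True):
        w = grp["area"].to_numpy(dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"stratum {sid!r}: all-zero overlap weights")
        rows.append({"stratum_id": sid, "year": int(year),
                     "sscd": float(np.average(grp["sscd"], weights=w))})
    return pd.DataFrame(rows)


def sscd_panel(sscd: pd.DataFrame) -> CovariatePanel:
    """Wrap a stratum-year SSCD table as a covariate panel."""
    return CovariatePanel(name="sscd",
                          data=sscd.rename(columns={"sscd": "value"}))


def sscd_phenology_correlation(sscd: pd.DataFrame,
                               phenology_panel: CovariatePanel,
                               min_years: int = 3) -> CorrelationSummary:
    """Mean across-strata Pearson r between SSCD and SOS (or DOP)."""
    return pair_correlation(sscd_panel(sscd), phenology_panel,
                            min_years=min_years)
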