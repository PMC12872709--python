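"""Run configuration: species set, strata, generator truth and thresholds.

Defaults mirror the study design the pipeline emulates: a 38-year
panel (1982-2019) of eight boreal duck species or species groups across
survey strata spanning a broad latitudinal gradient, with the scoter
series ending in 2012 (aerial estimates discontinued).  All values can
be overridden from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .synth import StratumSpec

DEFAULT_SPECIES = {
    "mallard": (1982, 2019),
    "goldeneye": (1982, 2019),
    "bufflehead": (1982, 2019),
    "green_winged_teal": (1982, 2019),
    "ring_necked_duck": (1982, 2019),
    "american_wigeon": (1982, 2019),
    "scaup": (1982, 2019),
    "scoter": (1982, 2012),
}


def default_strata(n: int = 12, n_pixels: int = 3) -> list[StratumSpec]:
    """Evenly spaced stratum centroids over the boreal latitude gradient."""
    out = []
    for i in range(n):
        lat = 54.0 + 14.0 * i / max(n - 1, 1)
        area = 30000.0 + 4000.0 * i
        out.append(StratumSpec(stratum_id=f"s{i + 1:02d}", latitude=lat,
                               area=area, n_pixels=n_pixels))
    return out


class SchemaError(ValueError):
    """A configuration block or field is missing or out of range."""


@dataclass
class SeasonConfig:
    """Generator for stratum-year seasonal curves.

    The rise midpoint shifts later with latitude and jitters between
    years (shared year anomaly + stratum-year noise), which induces the
    real-data pattern of spatially coherent early/late springs.
    """

    baseline: float = 0.2
    amplitude: float = 0.5
    rise_midpoint: float = 135.0
    rise_rate: float = 0.12
    fall_midpoint: float = 265.0
    fall_rate: float = 0.10
    noise_sd: float = 0.02
    lat_day_shift: float = 1.5      # days later per degree north
    interannual_sd: float = 6.0     # shared year anomaly of spring timing, days
    stratum_year_sd: float = 3.0    # independent stratum-year jitter, days
    fall_interannual_sd: float = 5.0
    amplitude_cv: float = 0.08      # relative interannual amplitude variation


@dataclass
class SnowConfig:
    melt_window: float = 28.0
    melt_offset: float = 10.0       # melt day precedes the NDVI rise midpoint


@dataclass
class DuckConfig:
    """Gompertz generating parameters shared by all species unless overridden."""

    alpha: float = 1.0
    theta_mean: float = 0.5
    sigma_theta: float = 0.05
    sigma_stratum: float = 0.1
    sigma_year: float = 0.1
    sigma_resid: float = 0.2
    beta_main: float = 0.0
    beta_lat: float = 0.0
    obs_sd: float = 0.0
    driver: str = "spring_timing"   # latent driver: standardized true rise midpoint
    x0: float = 2.0
    per_species: dict = field(default_factory=dict)  # name -> overrides


@dataclass
class Thresholds:
    amplitude_floor: float = 0.05
    season_threshold: float = 0.25  # fraction of amplitude defining SOS/EOS
    q_threshold: float = 0.05
    interaction_gate: float = 0.05
    min_recorded: int = 5


@dataclass
class RunConfig:
    seed: int = 0
    years: tuple[int, int] = (1982, 2019)
    species: dict = field(default_factory=lambda: dict(DEFAULT_SPECIES))
    strata: list = field(default_factory=default_strata)
    season: SeasonConfig = field(default_factory=SeasonConfig)
    snow: SnowConfig = field(default_factory=SnowConfig)
    duck: DuckConfig = field(default_factory=DuckConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self):
        self.validate()

    def validate(self):
        if not self.species:
            raise SchemaError("species: at least one species block required")
        y0, y1 = self.years
        if y1 <= y0:
            raise SchemaError("years: end must exceed start")
        for name, rng in self.species.items():
            a, b = rng
            if not (y0 <= a < b <= y1):
                raise SchemaError(
                    f"species.{name}.years: [{a}, {b}] outside run years {self.years}")
        if not self.strata:
            raise SchemaError("strata: at least one stratum required")
        th = self.thresholds
        for fname in ("season_threshold", "q_threshold", "interaction_gate"):
            v = getattr(th, fname)
            if not (0.0 < v < 1.0):
                raise SchemaError(f"thresholds.{fname}: must lie in (0, 1)")
        if th.min_recorded < 0:
            raise SchemaError("thresholds.min_recorded: must be >= 0")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def species_years(self, name: str) -> list[int]:
        a, b = self.species[name]
        return list(range(a, b + 1))

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strata"] = [asdict(s) for s in self.strata]
        d["years"] = list(self.years)
        d["species"] = {k: list(v) for k, v in self.species.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            if "strata" in d:
                d["strata"] = [StratumSpec(**s) for s in d["strata"]]
            if "years" in d:
                d["years"] = tuple(d["years"])
            if "species" in d:
                d["species"] = {k: tuple(v) for k, v in d["species"].items()}
            for key, klass in (("season", SeasonConfig), ("snow", SnowConfig),
                               ("duck", DuckConfig), ("thresholds", Thresholds)):
                if key in d and isinstance(d[key], dict):
                    d[key] = klass(**d[key])
            return cls(**d)
        except TypeError as exc:
            raise SchemaError(f"invalid configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
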