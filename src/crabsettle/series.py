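"""Canonical in-memory containers for settlement and covariate series.

Both containers are thin wrappers over tidy pandas DataFrames; the
wrapper exists to validate the schema invariants once at construction
and to provide the per-site-year views the staged models need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SETTLEMENT_COLUMNS = ["site", "year", "date", "day", "lunar_day",
                      "rate", "observed"]
ENV_COLUMNS = ["site", "date", "u", "v", "a", "flux", "sea_max",
               "night", "lunar_day"]


@dataclass
class SettlementSeries:
    """Per-site daily settlement rates on a continuous daily index.

    ``data`` holds one row per site-year-day including unsampled (gap)
    days, which carry ``observed=False`` and ``rate=NaN``.  ``rate`` is
    mean megalopae per collector per day, ``day`` the day of year
    (Jan 1 = 1) and ``lunar_day`` days since the last new moon (1..30).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SETTLEMENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"settlement table missing columns {missing}")
        df = self.data
        obs = df[df["observed"]]
        if (obs["rate"] < 0).any():
            raise ValueError("negative settlement rates")
        if not df["lunar_day"].between(1, 30).all():
            raise ValueError("lunar_day outside 1..30")
        dup = df.duplicated(subset=["site", "date"])
        if dup.any():
            raise ValueError("duplicate site-date rows")
        for (_, _), g in df.groupby(["site", "year"]):
            d = pd.to_datetime(g["date"])
            if not d.is_monotonic_increasing:
                raise ValueError("dates not increasing within site-year")
            doy = d.dt.dayofyear
            if not (doy.values == g["day"].values).all():
                raise ValueError("day column inconsistent with date")

    @property
    def site_years(self) -> list[tuple[str, int]]:
        return sorted({(s, int(y)) for s, y in
                       zip(self.data["site"], self.data["year"])})

    def observed(self) -> pd.DataFrame:
        """Rows for sampled days only."""
        return self.data[self.data["observed"]].copy()

    def site_year(self, site: str, year: int) -> pd.DataFrame:
        df = self.data
        return df[(df["site"] == site) & (df["year"] == year)].copy()


@dataclass
class EnvSeries:
    """Daily derived covariates per site (wind components, sea-level
    metrics, lunar day)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ENV_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"covariate table missing columns {missing}")
        if (self.data["flux"].dropna() < 0).any():
            raise ValueError("negative sea-level flux")
        if not self.data["lunar_day"].between(1, 30).all():
            raise ValueError("lunar_day outside 1..30")

    def site(self, site: str) -> pd.DataFrame:
        return self.data[self.data["site"] == site].copy()


@dataclass(frozen=True)
class WeightSample:
    """One pooled biweekly dry-weight sample."""

    site: str
    year: int
    interval: int
    n_individuals: int
    total_mass: float
    per_individual: float

    def __post_init__(self) -> None:
        if self.n_individuals not in (20, 100):
            raise ValueError("pooled samples contain 20 or 100 individuals")
        if self.total_mass < 0:
            raise ValueError("negative mass")
        if not np.isclose(self.per_individual,
                          self.total_mass / self.n_individuals):
            raise ValueError("per_individual inconsistent with total/n")
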