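"""CSV readers and writers for the pipeline's tidy tables.

All tables are plain CSV with ISO-8601 dates.  Schemas:

* settlement: site, date, rate (one row per sampled site-day; the
  reader reconstructs the continuous daily index, day-of-year and lunar
  day and masks unsampled days)
* hourly sea level: station, timestamp, height
* daily wind: station, date, ws, theta
* new moons: date (one per row)
"""

from __future__ import annotations

import json
from datetime import date as Date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import lunar_day
from .series import SettlementSeries


class SettlementReadError(ValueError):
    """Malformed settlement input, reported with line numbers."""


def read_settlement_csv(path, new_moons) -> SettlementSeries:
    """Read and validate a settlement CSV into a gap-masked series.

    The file needs columns site, date (ISO-8601) and rate.  Within each
    site-year, days between the first and last sampled date that carry
    no row are treated as unsampled (gap) days.  Duplicate site-dates
    and negative rates are hard errors naming the offending line.
    """
    df = pd.read_csv(path)
    required = {"site", "date", "rate"}
    missing = required - set(df.columns)
    if missing:
        raise SettlementReadError(
            f"{path}: missing columns {sorted(missing)}")
    df["_line"] = df.index + 2  # header is line 1
    try:
        df["date"] = pd.to_datetime(df["date"]).dt.date
    except (ValueError, TypeError) as exc:
        raise SettlementReadError(f"{path}: unparseable date: {exc}")
    bad = df[df["rate"] < 0]
    if not bad.empty:
        raise SettlementReadError(
            f"{path}: negative rate at line {int(bad['_line'].iloc[0])}")
    dup = df[df.duplicated(subset=["site", "date"], keep=False)]
    if not dup.empty:
        raise SettlementReadError(
            f"{path}: duplicate site-date at line "
            f"{int(dup['_line'].iloc[1])}")

    frames = []
    df["year"] = [d.year for d in df["date"]]
    for (site, year), grp in df.groupby(["site", "year"]):
        grp = grp.sort_values("date")
        start, end = grp["date"].iloc[0], grp["date"].iloc[-1]
        full = [start + timedelta(days=i)
                for i in range((end - start).days + 1)]
        rates = dict(zip(grp["date"], grp["rate"]))
        frames.append(pd.DataFrame({
            "site": site, "year": int(year), "date": full,
            "day": [d.timetuple().tm_yday for d in full],
            "lunar_day": [lunar_day(d, new_moons) for d in full],
            "rate": [rates.get(d, np.nan) for d in full],
            "observed": [d in rates for d in full],
        }))
    return SettlementSeries(pd.concat(frames, ignore_index=True))


def write_settlement_csv(series: SettlementSeries, path) -> None:
    obs = series.observed()
    obs[["site", "date", "rate"]].to_csv(path, index=False,
                                         float_format="%.15g")


def read_new_moons(path) -> list[Date]:
    df = pd.read_csv(path)
    return sorted(pd.to_datetime(df["date"]).dt.date)


def write_new_moons(moons, path) -> None:
    pd.DataFrame({"date": sorted(moons)}).to_csv(path, index=False)


def read_env_csv(path):
    """Read a daily covariate table written by the pipeline."""
    from .series import EnvSeries

    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return EnvSeries(df)


def read_hourly_sea_level(path) -> pd.DataFrame:
    """Buoy-style hourly water level: station, timestamp, height (m)."""
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_daily_wind(path, direction_convention: str = "toward"
                    ) -> pd.DataFrame:
    """Buoy-style daily wind: station, date, ws (m/s), theta (degrees).

    ``direction_convention="from"`` rotates meteorological
    "direction from" records by 180 degrees into the vector convention
    the wind-component formulas assume.
    """
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if direction_convention == "from":
        df["theta"] = (df["theta"] + 180.0) % 360.0
    elif direction_convention != "toward":
        raise ValueError(
            f"unknown direction convention {direction_convention!r}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.15g")


def write_manifest(path, **entries) -> None:
    """Run manifest: config hash, seed, package versions."""
    import statsmodels

    payload = {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        **entries,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
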