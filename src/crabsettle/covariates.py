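"""Derived physical covariates: wind components, sea-level metrics, lunar day.

All daily hydrodynamic and wind variables used by the settlement models
are computed here from raw hourly sea-level records, daily wind records
and a new-moon ephemeris.

Conventions
-----------
* Wind direction ``theta`` is the vector ("blowing toward") direction in
  degrees clockwise from true north, so that ``u = ws*cos(theta)`` is the
  northward component and ``v = ws*sin(theta)`` the eastward component.
  Buoy "direction from" records must be rotated by 180 degrees before
  they reach this module.
* The alongshore component is ``a = ws*cos(theta - x)`` where ``x`` is
  the local coastline's angle to true north; positive values favour
  landward Ekman transport.
* Lunar day is 1-based: a new-moon date has lunar day 1, and the count
  is capped at 30 so a 29.53-day synodic cycle always maps into 1..30.
* The night sea-level window covers 20:00-06:00 local inclusive.  By
  default observations are grouped by civil day (hours <= 06 and >= 20 of
  the same date), matching a per-calendar-day aggregation of buoy
  records; ``night_attribution="start-day"`` instead assigns the whole
  20:00->06:00 span to the day on which the night begins.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from datetime import date as Date, timedelta

import numpy as np
import pandas as pd

#: Minimum hourly observations required before a day's sea-level metrics
#: are considered valid.
MIN_HOURS_PER_DAY = 18

NIGHT_START_HOUR = 20  # inclusive
NIGHT_END_HOUR = 6     # inclusive


def wind_components(ws: float, theta: float, coast_angle: float
                    ) -> tuple[float, float, float]:
    """North-south, east-west and alongshore wind components.

    Parameters
    ----------
    ws : float
        Daily mean wind speed, m/s; must be non-negative.
    theta : float
        Daily mean wind direction toward which the wind blows, degrees
        clockwise from true north.
    coast_angle : float
        Local coastline angle to true north, degrees.

    Returns
    -------
    (u, v, a) : tuple of float
        u = ws*cos(theta), v = ws*sin(theta), a = ws*cos(theta - x).
    """
    if ws < 0:
        raise ValueError(f"wind speed must be non-negative, got {ws}")
    th = math.radians(theta)
    u = ws * math.cos(th)
    v = ws * math.sin(th)
    a = ws * math.cos(th - math.radians(coast_angle))
    return u, v, a


@dataclass(frozen=True)
class SeaLevelDay:
    """Daily sea-level metrics for one civil day."""
    date: Date
    flux: float
    sea_max: float
    night: float
    n_obs: int
    valid: bool


def sea_level_metrics(hourly, night_attribution: str = "calendar",
                      min_hours: int = MIN_HOURS_PER_DAY) -> SeaLevelDay:
    """Metrics for a single civil day of hourly (timestamp, height) pairs.

    ``flux`` is max minus min height over the day, ``sea_max`` the
    maximum, ``night`` the mean over the night window.  Days with fewer
    than ``min_hours`` observations are returned with ``valid=False``.
    """
    obs = [(pd.Timestamp(t), float(h)) for t, h in hourly]
    if not obs:
        raise ValueError("empty hourly record")
    times = [t for t, _ in obs]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("timestamps must be strictly increasing")
    days = {t.date() for t in times}
    if len(days) > 1 and night_attribution == "calendar":
        raise ValueError("sea_level_metrics expects a single civil day")
    day = min(days)
    heights = np.array([h for _, h in obs])
    flux = float(heights.max() - heights.min())
    sea_max = float(heights.max())
    night_vals = [h for t, h in obs
                  if t.hour >= NIGHT_START_HOUR or t.hour <= NIGHT_END_HOUR]
    night = float(np.mean(night_vals)) if night_vals else float("nan")
    return SeaLevelDay(day, flux, sea_max, night, len(obs),
                       valid=len(obs) >= min_hours)


def daily_sea_level(hourly: pd.DataFrame,
                    night_attribution: str = "calendar",
                    min_hours: int = MIN_HOURS_PER_DAY) -> pd.DataFrame:
    """Collapse an hourly sea-level table to daily flux/max/night metrics.

    Parameters
    ----------
    hourly : DataFrame
        Columns ``timestamp`` (datetime-like) and ``height`` (m).
    night_attribution : {"calendar", "start-day"}
        See module docstring.

    Returns
    -------
    DataFrame with columns date, flux, sea_max, night, n_obs, valid —
    one row per civil day present in the input.
    """
    if night_attribution not in ("calendar", "start-day"):
        raise ValueError(f"unknown night_attribution {night_attribution!r}")
    df = hourly.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values("timestamp")
    df["date"] = df["timestamp"].dt.date
    df["hour"] = df["timestamp"].dt.hour

    grouped = df.groupby("date")
    flux = grouped["height"].max() - grouped["height"].min()
    sea_max = grouped["height"].max()
    n_obs = grouped["height"].size()

    if night_attribution == "calendar":
        night_mask = (df["hour"] >= NIGHT_START_HOUR) | (df["hour"] <= NIGHT_END_HOUR)
        night = df[night_mask].groupby("date")["height"].mean()
    else:
        night_day = df["date"].where(
            df["hour"] >= NIGHT_START_HOUR,
            df["date"].map(lambda d: d - timedelta(days=1)))
        night_mask = (df["hour"] >= NIGHT_START_HOUR) | (df["hour"] <= NIGHT_END_HOUR)
        night = (df[night_mask].assign(night_day=night_day[night_mask])
                 .groupby("night_day")["height"].mean())

    out = pd.DataFrame({
        "date": flux.index,
        "flux": flux.values,
        "sea_max": sea_max.values,
        "night": night.reindex(flux.index).values,
        "n_obs": n_obs.values,
    })
    out["valid"] = out["n_obs"] >= min_hours
    return out.reset_index(drop=True)


def lunar_day(date: Date, new_moons) -> int:
    """Days since the most recent new moon, 1-based and capped at 30."""
    moons = sorted(new_moons)
    if not moons:
        raise ValueError("empty ephemeris")
    i = bisect_right(moons, date)
    if i == 0:
        raise ValueError(f"{date} precedes first ephemeris entry {moons[0]}")
    last = moons[i - 1]
    return min((date - last).days + 1, 30)


def build_env_series(site: str, coast_angle: float,
                     hourly_sea_level: pd.DataFrame,
                     daily_wind: pd.DataFrame,
                     new_moons,
                     night_attribution: str = "calendar") -> pd.DataFrame:
    """Assemble the tidy daily covariate table for one site.

    Parameters
    ----------
    hourly_sea_level : DataFrame with timestamp, height.
    daily_wind : DataFrame with date, ws, theta.
    new_moons : iterable of dates.

    Returns
    -------
    DataFrame with columns site, date, u, v, a, flux, sea_max, night,
    lunar_day; only days with valid sea-level metrics are kept.
    """
    sea = daily_sea_level(hourly_sea_level, night_attribution)
    sea = sea[sea["valid"]].drop(columns=["n_obs", "valid"])

    wind = daily_wind.copy()
    wind["date"] = pd.to_datetime(wind["date"]).dt.date
    if (wind["ws"] < 0).any():
        raise ValueError("negative wind speed in daily wind table")
    comp = wind.apply(
        lambda r: wind_components(r["ws"], r["theta"], coast_angle),
        axis=1, result_type="expand")
    comp.columns = ["u", "v", "a"]
    wind = pd.concat([wind[["date"]], comp], axis=1)

    env = sea.merge(wind, on="date", how="inner")
    env["lunar_day"] = [lunar_day(d, new_moons) for d in env["date"]]
    env.insert(0, "site", site)
    return env[["site", "date", "u", "v", "a",
                "flux", "sea_max", "night", "lunar_day"]]
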