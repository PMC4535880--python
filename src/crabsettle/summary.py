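"""Site-year summary statistics, pulse detection and dry-weight
standardisation."""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date

import numpy as np
import pandas as pd

from .series import SettlementSeries, WeightSample


@dataclass(frozen=True)
class SettlementSummary:
    """Summary of one site-year of daily settlement (sampled days only)."""

    site: str
    year: int
    start_date: Date
    median: float
    mean: float
    max: float
    sd: float
    n_pulses: int
    n_days: int


def detect_pulses(rates: np.ndarray, dates=None):
    """Days whose settlement exceeds the series mean plus two standard
    deviations (sample SD, n-1); strictly greater than the threshold.

    Returns the dates of pulse days (or integer positions when no dates
    are given).
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < 3:
        raise ValueError("pulse detection needs >= 3 sampled days")
    sd = float(np.std(rates, ddof=1))
    threshold = float(np.mean(rates)) + 2.0 * sd
    idx = np.nonzero(rates > threshold)[0]
    if dates is None:
        return idx.tolist()
    dates = np.asarray(dates)
    return list(dates[idx])


def settlement_summary(series: SettlementSeries) -> pd.DataFrame:
    """Per-site-year summary table: start date, median, mean, max, SD
    (sample, n-1) and pulse count over sampled days."""
    rows = []
    for (site, year), grp in series.observed().groupby(["site", "year"]):
        rates = grp["rate"].to_numpy(dtype=float)
        if rates.size < 2:
            raise ValueError(
                f"site {site} year {year}: need >= 2 sampled days")
        n_pulses = len(detect_pulses(rates)) if rates.size >= 3 else 0
        rows.append(SettlementSummary(
            site, int(year), grp["date"].iloc[0],
            float(np.median(rates)), float(np.mean(rates)),
            float(np.max(rates)), float(np.std(rates, ddof=1)),
            n_pulses, int(rates.size)))
    tab = pd.DataFrame([r.__dict__ for r in rows])
    return tab[["site", "year", "start_date", "median", "mean", "max",
                "sd", "n_pulses", "n_days"]]


def standardize_weights(pooled, site: str = "", year: int = 0
                        ) -> list[WeightSample]:
    """Convert pooled biweekly (interval, count, total mass) records to
    standardised per-individual weights.

    Intervals with >= 100 collected individuals are represented by
    100-individual samples, those with 20-99 by 20-individual samples,
    and those with < 20 are dropped.  ``total mass`` is the mass of the
    pooled sample actually weighed (mg).
    """
    out = []
    for interval, count, mass in pooled:
        if count <= 0:
            raise ValueError(f"interval {interval}: count must be positive")
        if mass < 0:
            raise ValueError(f"interval {interval}: negative mass")
        if count >= 100:
            n = 100
        elif count >= 20:
            n = 20
        else:
            continue
        out.append(WeightSample(site, year, int(interval), n,
                                float(mass), float(mass) / n))
    return out


def weight_table(samples: list[WeightSample]) -> pd.DataFrame:
    """Tidy table of per-individual dry weights."""
    return pd.DataFrame([{
        "site": s.site, "year": s.year, "interval": s.interval,
        "n_individuals": s.n_individuals, "total_mass": s.total_mass,
        "per_individual": s.per_individual} for s in samples])
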