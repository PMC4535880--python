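"""Synthetic multi-site settlement, covariate and dry-weight generator.

The generator produces data with the structure the staged settlement
models assume, with known ground truth so every downstream stage can be
tested against the parameters that produced its input:

* log(rate + 1) = site intercept + annual sin/cos harmonic + lunar
  harmonic (sin, cos, sin*cos at the true 29.53-day synodic period)
  + centred covariate effects + AR(1) noise + rare pulse shocks,
  exponentiated back to a non-negative daily rate;
* two consecutive unsampled days per seven-day block (weekend gaps);
* hourly sea level as a diurnal tide whose amplitude is modulated at the
  lunar period, plus noise; daily winds as a bivariate AR(1) weakly
  coupled to the tidal range;
* biweekly pooled dry-weight samples of 100 (or 20) individuals with a
  mid-season dip in individual mass.

Randomness derives from a single root seed via per-site child streams,
so adding a site leaves the other sites' data unchanged.
"""

from __future__ import annotations

import math
from datetime import date as Date, datetime, timedelta

import numpy as np
import pandas as pd

from .config import (EPHEMERIS_EPOCH, SYNODIC_MONTH, SimulationConfig,
                     SiteConfig, synodic_new_moons)
from .covariates import build_env_series, lunar_day
from .series import EnvSeries, SettlementSeries, WeightSample

TWO_PI = 2.0 * math.pi


_STREAM_NAMES = ("env", "settle", "pulse", "weight")


def _site_streams(config: SimulationConfig) -> dict[str, dict]:
    """Per-site labelled child seed sequences from the single root seed."""
    root = np.random.SeedSequence(config.seed)
    site_seqs = root.spawn(len(config.sites))
    out = {}
    for s, seq in zip(config.sites, site_seqs):
        children = seq.spawn(len(_STREAM_NAMES))
        out[s.name] = dict(zip(_STREAM_NAMES, children))
    return out


def _lunar_fraction(dates: pd.Series) -> np.ndarray:
    """Continuous phase in [0, 1) of the true synodic cycle, anchored at
    the ephemeris epoch (a real new moon)."""
    anchor = EPHEMERIS_EPOCH.toordinal()
    ords = np.array([d.toordinal() for d in dates], dtype=float)
    return ((ords - anchor) / SYNODIC_MONTH) % 1.0


def _season_days(site: SiteConfig, year: int) -> pd.DataFrame:
    start, end = site.season_bounds(year)
    dates = [start + timedelta(days=i) for i in range((end - start).days + 1)]
    return pd.DataFrame({"date": dates,
                         "day": [d.timetuple().tm_yday for d in dates],
                         "idx": np.arange(len(dates))})


def _new_moons_for(site: SiteConfig, year: int) -> list[Date]:
    start, end = site.season_bounds(year)
    return synodic_new_moons(start - timedelta(days=35), end)


def generate_environment(config: SimulationConfig,
                         _streams=None) -> tuple[EnvSeries, pd.DataFrame]:
    """Generate hourly sea level and daily wind, return derived covariates.

    Returns
    -------
    (EnvSeries, DataFrame)
        The daily covariate table (via the covariates module) and the
        raw hourly sea-level table (site, timestamp, height).
    """
    config.validate()
    streams = _streams if _streams is not None else _site_streams(config)
    env_frames, hourly_frames = [], []
    for site in config.sites:
        rng = np.random.default_rng(streams[site.name]["env"])
        for year in site.years:
            days = _season_days(site, year)
            moons = _new_moons_for(site, year)
            lf = _lunar_fraction(days["date"])
            n = len(days)

            # hourly sea level: diurnal tide, lunar-modulated amplitude
            amp = config.tide_amplitude * (
                1.0 + config.tide_lunar_mod * np.sin(TWO_PI * lf))
            hours = np.arange(24)
            ts, heights = [], []
            noise = rng.normal(0.0, config.sea_level_noise_sd, size=(n, 24))
            for i, d in enumerate(days["date"]):
                base = datetime(d.year, d.month, d.day)
                ts.extend(base + timedelta(hours=int(h)) for h in hours)
                heights.append(amp[i] * np.sin(TWO_PI * hours / 24.0)
                               + noise[i])
            hourly = pd.DataFrame({"timestamp": ts,
                                   "height": np.concatenate(heights)})

            # daily wind: bivariate AR(1) on (u, v), weakly coupled to
            # the tidal range through the shared lunar modulation
            u = np.empty(n)
            v = np.empty(n)
            sd_stat = config.wind_sd / math.sqrt(1 - config.wind_ar ** 2)
            u[0] = rng.normal(0.0, sd_stat)
            v[0] = rng.normal(0.0, sd_stat)
            eps = rng.normal(0.0, config.wind_sd, size=(n, 2))
            for i in range(1, n):
                u[i] = config.wind_ar * u[i - 1] + eps[i, 0]
                v[i] = config.wind_ar * v[i - 1] + eps[i, 1]
            u = (u + config.wind_mean_u
                 + config.wind_lunar_coupling * np.sin(TWO_PI * lf))
            v = v + config.wind_mean_v
            ws = np.hypot(u, v)
            theta = np.degrees(np.arctan2(v, u)) % 360.0
            wind = pd.DataFrame({"date": days["date"], "ws": ws,
                                 "theta": theta})

            env = build_env_series(site.name, site.coastline_angle,
                                   hourly, wind, moons)
            env["year"] = year
            env_frames.append(env)
            hourly.insert(0, "site", site.name)
            hourly_frames.append(hourly)
    env_all = pd.concat(env_frames, ignore_index=True)
    return EnvSeries(env_all), pd.concat(hourly_frames, ignore_index=True)


def generate_settlement(config: SimulationConfig,
                        return_env: bool = False):
    """Generate the daily settlement series (and, optionally, covariates).

    The settlement log-process adds, to the deterministic harmonic
    surface, centred environmental effects and AR(1) noise; the rate is
    ``exp(eta) - 1`` floored at zero, and gap days are marked unobserved.
    Identical config and seed give bit-identical output.
    """
    config.validate()
    streams = _site_streams(config)
    env, hourly = generate_environment(config, _streams=streams)

    rows = []
    for site in config.sites:
        rng = np.random.default_rng(streams[site.name]["settle"])
        prng = np.random.default_rng(streams[site.name]["pulse"])
        env_site = env.site(site.name)
        for year in site.years:
            days = _season_days(site, year)
            moons = _new_moons_for(site, year)
            lf = _lunar_fraction(days["date"])
            n = len(days)

            a_s, b_s = site.seasonal
            a_l, b_l, c_l = site.lunar
            ann = TWO_PI * days["day"].to_numpy() / 365.0
            lun = TWO_PI * lf
            seasonal = a_s * np.sin(ann) + b_s * np.cos(ann)
            lunar = (a_l * np.sin(lun) + b_l * np.cos(lun)
                     + c_l * np.sin(lun) * np.cos(lun))

            ev = env_site[env_site["year"] == year].set_index("date")
            ev = ev.reindex(days["date"])
            env_part = np.zeros(n)
            for name, coef in config.env_effects.items():
                if coef == 0.0:
                    continue
                x = ev[name].to_numpy(dtype=float)
                x = np.where(np.isnan(x), np.nanmean(x), x)
                env_part = env_part + coef * (x - np.nanmean(x))

            eps = np.zeros(n)
            if config.noise_sd > 0:
                innov = rng.normal(0.0, config.noise_sd, size=n)
                phi = config.ar_coef
                eps[0] = innov[0] / math.sqrt(1 - phi ** 2)
                for i in range(1, n):
                    eps[i] = phi * eps[i - 1] + innov[i]

            pulse = np.zeros(n)
            if config.pulse_rate > 0:
                n_pulses = prng.poisson(config.pulse_rate)
                if n_pulses > 0:
                    idx = prng.choice(n, size=min(n_pulses, n), replace=False)
                    pulse[idx] = config.pulse_log_shock

            eta = (site.mean_log_rate + seasonal + lunar + env_part
                   + eps + pulse)
            rate = np.maximum(np.exp(eta) - 1.0, 0.0)
            observed = (days["idx"].to_numpy() % 7) < (7 - config.sampling_gap)
            ld = np.array([lunar_day(d, moons) for d in days["date"]])
            rows.append(pd.DataFrame({
                "site": site.name, "year": year, "date": days["date"],
                "day": days["day"], "lunar_day": ld,
                "rate": np.where(observed, rate, np.nan),
                "observed": observed,
                # ground-truth log-scale components, for recovery tests
                "true_log1p": np.log1p(rate),
                "true_seasonal": seasonal,
                "true_lunar": lunar,
                "true_env": env_part,
                "true_ar": eps,
                "true_pulse": pulse,
            }))
    settlement = SettlementSeries(pd.concat(rows, ignore_index=True))
    if return_env:
        return settlement, env, hourly
    return settlement


def generate_weight_samples(config: SimulationConfig,
                            settlement: SettlementSeries | None = None
                            ) -> list[WeightSample]:
    """Biweekly pooled dry-weight samples per site-year.

    Intervals are anchored at each site-year's first sampled date.  The
    number of individuals available in an interval is taken from the
    simulated settlement (sum of observed daily rates, i.e. per-collector
    catch); intervals with >= 100 use 100, with 20..99 use 20, and with
    < 20 are absent.  Individual masses are normal around the site mean
    with a mid-season dip.
    """
    config.validate()
    if settlement is None:
        settlement = generate_settlement(config)
    streams = _site_streams(config)
    out: list[WeightSample] = []
    for site in config.sites:
        rng = np.random.default_rng(streams[site.name]["weight"])
        for year in site.years:
            sy = settlement.site_year(site.name, year)
            sampled = sy[sy["observed"]]
            if sampled.empty:
                continue
            start = sampled["date"].iloc[0]
            interval = ((sampled["date"] - start)
                        .map(lambda td: td.days) // 14)
            for k, grp in sampled.groupby(interval):
                available = int(grp["rate"].sum())
                if available >= 100:
                    n_ind = 100
                elif available >= 20:
                    n_ind = 20
                else:
                    continue
                mid_day = float(grp["day"].mean())
                dip = config.weight_season_dip * math.sin(
                    TWO_PI * (mid_day - 140.0) / 365.0)
                mean_mass = max(site.weight_mean - dip, 1e-3)
                masses = rng.normal(mean_mass, config.weight_sd, size=n_ind)
                masses = np.maximum(masses, 0.0)
                total = float(masses.sum())
                out.append(WeightSample(site.name, year, int(k), n_ind,
                                        total, total / n_ind))
    return out


def generate_all(config: SimulationConfig):
    """Convenience wrapper returning settlement, covariates, hourly sea
    level and weight samples from one seeded run."""
    settlement, env, hourly = generate_settlement(config, return_env=True)
    weights = generate_weight_samples(config, settlement)
    return settlement, env, hourly, weights
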