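"""Configuration objects for simulation and analysis runs.

The simulation is organised around a list of sites, each with its own
sampling years, season window, coastline orientation and harmonic
amplitudes, plus shared dynamic parameters (autoregression, innovation
noise, covariate effects).  Defaults emulate a northern Gulf of Mexico
monitoring design: five coastal sites sampled daily (five days per week)
from late spring to the end of October, one site sampled in a single year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date

import yaml

#: Mean synodic month in days, used by the generator's ephemeris.
SYNODIC_MONTH = 29.530588

#: A real new-moon date used to anchor the synthetic ephemeris.
EPHEMERIS_EPOCH = date(2010, 1, 15)


@dataclass(frozen=True)
class SiteConfig:
    """Static description of one monitoring site.

    Parameters
    ----------
    name : str
        Site label.
    coastline_angle : float
        Angle of the local coastline to true north, degrees in [0, 360).
        Used for the alongshore wind projection.
    years : tuple of int
        Calendar years in which the site is sampled.
    season_start, season_end : str
        "MM-DD" bounds of the sampling season within each year.
    mean_log_rate : float
        Intercept of the site's log(rate + 1) process.
    seasonal : (float, float)
        Amplitudes (a_s, b_s) of sin and cos at the annual period (365 d).
    lunar : (float, float, float)
        Amplitudes (a_l, b_l, c_l) of sin, cos and sin*cos at the lunar
        period.
    weight_mean : float
        Mean dry weight per individual, mg.
    oiled : bool
        Whether the site lies within the surface-oil extent (an input
        label for the impact analyses, never computed).
    """

    name: str
    coastline_angle: float
    years: tuple[int, ...]
    season_start: str = "05-15"
    season_end: str = "10-31"
    mean_log_rate: float = 3.0
    seasonal: tuple[float, float] = (0.6, -0.6)
    lunar: tuple[float, float, float] = (0.35, 0.25, 0.15)
    weight_mean: float = 0.25
    oiled: bool = False

    def season_bounds(self, year: int) -> tuple[date, date]:
        m0, d0 = (int(p) for p in self.season_start.split("-"))
        m1, d1 = (int(p) for p in self.season_end.split("-"))
        return date(year, m0, d0), date(year, m1, d1)


def _default_sites() -> tuple[SiteConfig, ...]:
    # Five-site design: four sites sampled in two consecutive years plus
    # one single-year site, mirroring a realistic unbalanced monitoring
    # campaign.  Amplitudes differ by site so that site-bearing harmonic
    # structures are identifiable.
    return (
        SiteConfig("Galveston", 35.0, (2010, 2011), season_start="05-27",
                   mean_log_rate=2.0,
                   seasonal=(-0.5, 0.7), lunar=(-0.30, 0.25, 0.10),
                   weight_mean=0.28, oiled=False),
        SiteConfig("GrandIsle", 60.0, (2010, 2011), season_start="05-20",
                   mean_log_rate=4.0,
                   seasonal=(0.9, -0.7), lunar=(-0.40, 0.30, -0.15),
                   weight_mean=0.27, oiled=True),
        SiteConfig("Dauphin", 80.0, (2010, 2011), season_start="05-19",
                   mean_log_rate=3.8,
                   seasonal=(0.8, -0.9), lunar=(0.45, 0.30, 0.10),
                   weight_mean=0.20, oiled=True),
        SiteConfig("Pensacola", 85.0, (2010, 2011), season_start="05-18",
                   mean_log_rate=6.0,
                   seasonal=(0.7, -1.0), lunar=(0.40, 0.35, 0.20),
                   weight_mean=0.21, oiled=True),
        SiteConfig("Apalachicola", 70.0, (2010,), season_start="06-28",
                   mean_log_rate=1.9,
                   seasonal=(0.4, -1.1), lunar=(0.35, 0.20, 0.10),
                   weight_mean=0.28, oiled=False),
    )


@dataclass
class SimulationConfig:
    """Full specification of one synthetic data set.

    The defaults are chosen so that on the log scale the seasonal
    harmonic, lunar harmonic, autoregressive structure and environmental
    covariates contribute variance in roughly the proportions observed in
    northern Gulf settlement series (seasonal strongest, autoregression
    next, lunar moderate, environment weak).
    """

    sites: tuple[SiteConfig, ...] = field(default_factory=_default_sites)
    ar_coef: float = 0.6
    noise_sd: float = 0.7
    env_effects: dict = field(default_factory=lambda: {
        "flux": 1.0, "sea_max": 0.0, "night": 0.0, "u": 0.05})
    pulse_rate: float = 3.0
    pulse_log_shock: float = 2.5
    sampling_gap: int = 2
    weight_sd: float = 0.03
    weight_season_dip: float = 0.04
    # hourly sea-level process
    tide_amplitude: float = 0.40
    tide_lunar_mod: float = 0.35
    sea_level_noise_sd: float = 0.05
    # daily wind process (AR(1) on the u and v components)
    wind_ar: float = 0.5
    wind_sd: float = 2.0
    wind_mean_u: float = -0.5
    wind_mean_v: float = 0.5
    #: amplitude of the lunar-periodic component of the u wind (m/s);
    #: makes wind weakly covary with the tidal cycle
    wind_lunar_coupling: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not -1.0 < self.ar_coef < 1.0:
            raise ValueError(f"ar_coef must be in (-1, 1), got {self.ar_coef}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.pulse_rate < 0:
            raise ValueError("pulse_rate must be non-negative")
        if not 0 <= self.sampling_gap <= 6:
            raise ValueError("sampling_gap must be in 0..6")
        if not -1.0 < self.wind_ar < 1.0:
            raise ValueError("wind_ar must be in (-1, 1)")
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise ValueError("duplicate site names")
        for s in self.sites:
            if len(set(s.years)) != len(s.years):
                raise ValueError(f"duplicate years for site {s.name}")
            for y in s.years:
                start, end = s.season_bounds(y)
                n_days = (end - start).days + 1
                n_sampled = sum(1 for i in range(n_days)
                                if i % 7 < 7 - self.sampling_gap)
                if n_sampled < 60:
                    raise ValueError(
                        f"site {s.name} year {y} has only {n_sampled} "
                        "sampled days; need >= 60")

    @property
    def site_year_cells(self) -> list[tuple[str, int]]:
        return [(s.name, y) for s in self.sites for y in s.years]


def load_config(path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a declarative YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sites = raw.pop("sites", None)
    cfg_kwargs = dict(raw)
    if sites is not None:
        cfg_kwargs["sites"] = tuple(
            SiteConfig(**{**site, "years": tuple(site["years"]),
                          "seasonal": tuple(site.get("seasonal", (0.6, -0.6))),
                          "lunar": tuple(site.get("lunar", (0.35, 0.25, 0.15)))})
            for site in sites)
    cfg = SimulationConfig(**cfg_kwargs)
    cfg.validate()
    return cfg


def dump_config(cfg: SimulationConfig, path) -> None:
    payload = asdict(cfg)
    payload["sites"] = [asdict(s) for s in cfg.sites]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def synodic_new_moons(start: date, end: date,
                      epoch: date = EPHEMERIS_EPOCH,
                      synodic: float = SYNODIC_MONTH) -> list[date]:
    """New-moon dates between ``start`` and ``end`` on a mean synodic cycle.

    The ephemeris is a uniform 29.530588-day sequence anchored at a real
    new moon; dates are the calendar days containing each event.  The
    list always includes the last new moon at or before ``start`` so that
    a lunar day is defined for every date in the window.
    """
    if end < start:
        raise ValueError("end before start")
    out: list[date] = []
    k = int((start - epoch).days / synodic) - 2
    while True:
        d = epoch.toordinal() + k * synodic
        dd = date.fromordinal(int(d))
        if dd > end:
            break
        out.append(dd)
        k += 1
    # keep the most recent new moon before start plus everything inside
    prior = [d for d in out if d <= start]
    inside = [d for d in out if d > start]
    if not prior:
        raise ValueError("ephemeris does not cover start date")
    return [prior[-1]] + inside
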