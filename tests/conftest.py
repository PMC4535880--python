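"""Shared fixtures: small seeded simulation configs and the study design."""

from __future__ import annotations

import pytest

from crabsettle.config import SimulationConfig, SiteConfig


@pytest.fixture(scope="session")
def study_cells():
    """The five-site, two-year design with one single-year site."""
    sites = ["Galveston", "GrandIsle", "Dauphin", "Pensacola",
             "Apalachicola"]
    return frozenset((s, y) for s in sites for y in (2010, 2011)
                     if not (s == "Apalachicola" and y == 2011))


def small_sites(n_sites: int = 4, years=(2010, 2011)):
    amps = [(0.9, -0.5), (-0.6, 0.8), (0.5, 0.9), (1.0, -0.8)]
    lunar = [(0.4, 0.2, 0.1), (-0.3, 0.3, -0.1), (0.35, -0.25, 0.1),
             (0.3, 0.35, 0.15)]
    return tuple(
        SiteConfig(f"S{i}", 40.0 + 10 * i, tuple(years),
                   season_start="05-15", season_end="10-15",
                   mean_log_rate=3.0 + 0.4 * i,
                   seasonal=amps[i], lunar=lunar[i])
        for i in range(n_sites))


@pytest.fixture
def small_config():
    """Four sites, two years, ~130 sampled days per site-year."""
    return SimulationConfig(sites=small_sites(), seed=42)


@pytest.fixture(scope="session")
def default_data():
    """One seeded draw from the default study-like configuration."""
    from crabsettle.synthetic import generate_all

    cfg = SimulationConfig(seed=11)
    settlement, env, hourly, weights = generate_all(cfg)
    return cfg, settlement, env, hourly, weights
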