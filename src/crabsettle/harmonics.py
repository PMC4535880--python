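"""Harmonic (sine-cosine) regression with factorial Site/Year structure.

The seasonal model regresses log-transformed settlement on sin and cos of
the annual period (365 d); the lunar model regresses seasonal residuals
on sin, cos and sin*cos of a 30-day period.  Each harmonic term may be
crossed with Site and Year factors; ``"*"`` crossing is expanded as all
main effects and interactions (treatment coding, first level as
reference).  Columns that are identically zero because a site-year cell
is absent from the design (e.g. a site sampled in only one year) are
dropped before fitting, and the parameter count k is the number of
remaining columns plus one for the residual variance.

AIC is the Gaussian ML criterion, 2k - 2*logLik with the ML variance
estimate RSS/n.  Model selection takes the minimum-AIC fit, except that
when another candidate lies within 2 AIC units and has fewer parameters
the more parsimonious candidate is preferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

AIC_EQUIVALENCE = 2.0

#: harmonic term -> function of the phase angle (radians)
_TERM_FUNCS = {
    "sin": np.sin,
    "cos": np.cos,
    "sincos": lambda ang: np.sin(ang) * np.cos(ang),
}


@dataclass(frozen=True)
class HarmonicStructure:
    """One candidate model structure.

    Parameters
    ----------
    period : float
        Harmonic period in days (365 for seasonal, 30 for lunar).
    terms : tuple of str
        Harmonic terms entering the model, drawn from
        {"sin", "cos", "sincos"}; empty for the null (intercept-only)
        model.
    factors : tuple of str
        Factors fully crossed with every harmonic term, drawn from
        {"Site", "Year"}.
    cells : frozenset of (site, year)
        Site-year combinations present in the design; columns specific
        to absent cells are inestimable and dropped.
    name : str
        Human-readable label ("full", "site", "year", "plain", "null").
    """

    period: float
    terms: tuple[str, ...]
    factors: tuple[str, ...]
    cells: frozenset
    name: str = ""

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        bad = set(self.terms) - set(_TERM_FUNCS)
        if bad:
            raise ValueError(f"unknown harmonic terms {bad}")
        if set(self.factors) - {"Site", "Year"}:
            raise ValueError("factors must be a subset of {Site, Year}")

    @property
    def sites(self) -> list[str]:
        return sorted({s for s, _ in self.cells})

    @property
    def years(self) -> list[int]:
        return sorted({y for _, y in self.cells})


def candidate_structures(period: float, terms: tuple[str, ...],
                         cells) -> list[HarmonicStructure]:
    """The five candidate structures compared at each harmonic stage:
    full factorial (Site and Year), Site-only, Year-only, plain harmonic
    and null."""
    cells = frozenset(cells)
    return [
        HarmonicStructure(period, terms, ("Site", "Year"), cells, "full"),
        HarmonicStructure(period, terms, ("Site",), cells, "site"),
        HarmonicStructure(period, terms, ("Year",), cells, "year"),
        HarmonicStructure(period, terms, (), cells, "plain"),
        HarmonicStructure(period, (), (), cells, "null"),
    ]


def _column_specs(structure: HarmonicStructure):
    """Enumerate design columns as (harm, site_level, year_level) triples.

    ``harm=None`` denotes the intercept block (the crossing of the bare
    factors); ``site_level``/``year_level`` are non-reference factor
    levels or ``None`` when the factor does not enter that column.  The
    expansion of ``t*Site*Year`` therefore yields, for each harmonic
    term t and for the intercept block, every subset of the crossed
    factors with every combination of their non-reference levels.
    """
    sites = structure.sites
    years = structure.years
    nonref = {"Site": sites[1:], "Year": years[1:]}
    factor_subsets = []
    k = len(structure.factors)
    for mask in range(1 << k):
        subset = tuple(f for i, f in enumerate(structure.factors)
                       if mask >> i & 1)
        factor_subsets.append(subset)

    specs = []
    harms = (None,) + tuple(structure.terms)
    for harm in harms:
        # lower-order factor subsets first, so that aliasing caused by
        # absent cells is charged to the highest-order columns
        for subset in sorted(factor_subsets, key=len):
            level_axes = [nonref[f] for f in subset]
            for combo in product(*level_axes):
                site_level = year_level = None
                for f, lev in zip(subset, combo):
                    if f == "Site":
                        site_level = lev
                    else:
                        year_level = lev
                specs.append((harm, site_level, year_level))
    return specs


def _estimable_mask(structure: HarmonicStructure) -> np.ndarray:
    """Boolean mask of structurally estimable columns.

    An absent site-year cell makes some columns of the full crossing
    linear combinations of lower-order ones (with treatment coding the
    aliasing can fall on any block, depending on which levels are
    reference).  Estimability is decided by incremental rank over a
    covering pseudo-design: several distinct phase values in every
    present cell, so that only structural (cell-driven) aliasing — not
    accidental data collinearity — is detected.
    """
    cells = sorted(structure.cells)
    n_phase = max(len(structure.terms) + 2, 5)
    phases = np.linspace(0.1, 0.9, n_phase) * structure.period
    x = np.tile(phases, len(cells))
    site = np.repeat([s for s, _ in cells], n_phase)
    year = np.repeat([y for _, y in cells], n_phase)
    X, _ = _raw_design(structure, x, site, year)
    return _greedy_independent(X)


def _greedy_independent(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Mask of columns kept by greedy left-to-right rank selection."""
    n, p = X.shape
    basis = np.empty((n, 0))
    keep = np.zeros(p, dtype=bool)
    for j in range(p):
        c = X[:, j].astype(float)
        r = c - basis @ (basis.T @ c)
        # re-orthogonalise once for numerical safety
        r = r - basis @ (basis.T @ r)
        norm_c = np.linalg.norm(c)
        if norm_c > 0 and np.linalg.norm(r) > tol * norm_c:
            basis = np.column_stack([basis, r / np.linalg.norm(r)])
            keep[j] = True
    return keep


def count_parameters(structure: HarmonicStructure) -> int:
    """Number of estimated parameters k: estimable design columns plus
    one residual-variance parameter."""
    if not structure.cells:
        raise ValueError("empty site-year design")
    return int(_estimable_mask(structure).sum()) + 1


def _raw_design(structure: HarmonicStructure, x, site, year
                ) -> tuple[np.ndarray, list[str]]:
    ang = 2.0 * math.pi * np.asarray(x, dtype=float) / structure.period
    site = np.asarray(site)
    year = np.asarray(year)
    cols, names = [], []
    for harm, s_lev, y_lev in _column_specs(structure):
        col = np.ones(len(ang)) if harm is None else _TERM_FUNCS[harm](ang)
        label = harm or "1"
        if s_lev is not None:
            col = col * (site == s_lev)
            label += f":Site[{s_lev}]"
        if y_lev is not None:
            col = col * (year == y_lev)
            label += f":Year[{y_lev}]"
        cols.append(col)
        names.append(label)
    return np.column_stack(cols), names


def design_matrix(structure: HarmonicStructure, x, site, year
                  ) -> tuple[np.ndarray, list[str]]:
    """Estimable expanded design matrix for data rows (x, site, year).

    ``x`` is the phase variable (day of year, or lunar day).  Columns
    structurally aliased by absent site-year cells are already removed.
    """
    X, names = _raw_design(structure, x, site, year)
    keep = _estimable_mask(structure)
    return X[:, keep], [n for n, k in zip(names, keep) if k]


def gaussian_loglik(residuals: np.ndarray) -> float:
    """Gaussian log-likelihood at the ML variance estimate RSS/n."""
    resid = np.asarray(residuals, dtype=float)
    n = resid.size
    rss = float(resid @ resid)
    if rss <= 0.0:
        return math.inf
    sigma2 = rss / n
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


@dataclass
class HarmonicFit:
    """A fitted harmonic regression."""

    structure: HarmonicStructure
    coefficients: pd.Series
    k: int
    loglik: float
    aic: float
    residuals: np.ndarray
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def name(self) -> str:
        return self.structure.name


def fit_harmonic(y, structure: HarmonicStructure, x, site, year
                 ) -> HarmonicFit:
    """Ordinary least squares on the expanded factorial design.

    Raises if the design is rank deficient after estimability dropping:
    aliasing is reported, never silently pseudo-inverted.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    X, names = design_matrix(structure, x, site, year)
    if len(y) < X.shape[1] + 1:
        raise ValueError(
            f"{len(y)} observations cannot identify {X.shape[1]} columns")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for {structure.name!r}: rank {rank} "
            f"< {X.shape[1]} columns")
    fitted = X @ beta
    resid = y - fitted
    k = X.shape[1] + 1
    ll = gaussian_loglik(resid)
    aic = 2.0 * k - 2.0 * ll
    return HarmonicFit(structure, pd.Series(beta, index=names), k, ll,
                       aic, resid, fitted)


def select_model(fits: list[HarmonicFit]) -> HarmonicFit:
    """Minimum-AIC fit, with parsimony on AIC equivalence.

    Candidates within :data:`AIC_EQUIVALENCE` of the best AIC are
    treated as equivalent; among equivalents the fit with fewest
    parameters wins (ties broken by lower AIC).
    """
    if not fits:
        raise ValueError("no fitted candidates")
    best_aic = min(f.aic for f in fits)
    equiv = [f for f in fits if f.aic - best_aic <= AIC_EQUIVALENCE]
    return min(equiv, key=lambda f: (f.k, f.aic))


def delta_aic_table(fits: list[HarmonicFit]) -> pd.DataFrame:
    """AIC comparison table (model, k, AIC, dAIC), sorted by AIC."""
    rows = [{"model": f.structure.name, "k": f.k, "aic": f.aic}
            for f in fits]
    tab = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    return tab


def site_curve(fit: HarmonicFit, site: str, grid: np.ndarray) -> np.ndarray:
    """The site's fitted harmonic mean curve over phase values ``grid``,
    averaged over the years in which the site appears."""
    years = [y for s, y in fit.structure.cells if s == site]
    if not years:
        raise ValueError(f"site {site!r} not in design")
    curves = []
    for yr in years:
        X, _ = design_matrix(fit.structure, grid,
                             np.repeat(site, len(grid)),
                             np.repeat(yr, len(grid)))
        curves.append(X @ fit.coefficients.to_numpy())
    return np.mean(curves, axis=0)


def peak_day(fit: HarmonicFit, site: str, resolution: float = 0.001
             ) -> float:
    """Argmax of the site's fitted harmonic curve over one period.

    For the annual period the grid spans [0, 365); for the lunar period
    it spans [1, 31), so the result is a lunar day in 1..30.
    """
    period = fit.structure.period
    start = 1.0 if period <= 30.0 else 0.0
    grid = np.arange(start, start + period, resolution)
    curve = site_curve(fit, site, grid)
    if np.ptp(curve) < 1e-12:
        raise ValueError(f"site {site!r} has a flat (zero-amplitude) curve")
    return float(grid[int(np.argmax(curve))])
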