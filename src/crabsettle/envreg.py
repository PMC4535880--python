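"""Environmental regression: hydrodynamic and wind effects on whitened
settlement residuals.

The candidate model contains daily sea-level flux, maximum sea level,
mean night sea level, the north-south wind component, Year (when the
site has more than one year of data) and all second-order interactions.
Backward elimination by AIC prunes this full model while respecting
marginality: a main effect is never removed while an interaction
containing it remains.  The alongshore and east-west wind components are
excluded from the default candidate set (they were consistently
uninformative for settlement) but can be restored, as can 0-3 day lags
of the covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .harmonics import AIC_EQUIVALENCE

DEFAULT_MAIN_EFFECTS = ("flux", "sea_max", "night", "u")
EXTRA_WIND_EFFECTS = ("a", "v")


@dataclass
class EnvRegressionFit:
    """Result of the backward-eliminated environmental regression."""

    terms: tuple[str, ...]
    params: pd.Series
    pvalues: pd.Series
    aic: float
    resid: pd.Series = field(repr=False)
    nobs: int = 0

    @property
    def significant(self) -> pd.Series:
        """Coefficients flagged at p < 0.05 (intercept excluded)."""
        mask = (self.pvalues < 0.05) & (self.pvalues.index != "const")
        return self.params[mask[mask].index]


def _term_column(term: str, data: pd.DataFrame) -> np.ndarray:
    if ":" in term:
        a, b = term.split(":")
        return _term_column(a, data) * _term_column(b, data)
    if term == "year":
        years = sorted(data["year"].unique())
        return (data["year"] == years[-1]).astype(float).to_numpy()
    return data[term].astype(float).to_numpy()


def _build_design(terms, data: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame({t: _term_column(t, data) for t in terms},
                     index=data.index)
    X.insert(0, "const", 1.0)
    return X


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    model = sm.OLS(y, X)
    return model.fit()


def _removable(terms) -> list[str]:
    """Terms whose removal respects marginality."""
    parents = set()
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            parents.update((a, b))
    return [t for t in terms if ":" in t or t not in parents]


def candidate_terms(multi_year: bool, include_extra_wind: bool = False,
                    lags: int = 0) -> list[str]:
    """Full candidate term set: main effects plus all pairwise
    interactions; Year terms only for multi-year sites."""
    mains = list(DEFAULT_MAIN_EFFECTS)
    if include_extra_wind:
        mains += list(EXTRA_WIND_EFFECTS)
    for lag in range(1, lags + 1):
        mains += [f"{m}_lag{lag}" for m in DEFAULT_MAIN_EFFECTS]
    if multi_year:
        mains.append("year")
    inter = [f"{a}:{b}" for a, b in combinations(mains, 2)]
    return mains + inter


def fit_env_regression(resid: pd.Series, env: pd.DataFrame,
                       include_extra_wind: bool = False,
                       lags: int = 0) -> EnvRegressionFit:
    """Backward-eliminate the full environmental model by AIC.

    Parameters
    ----------
    resid : Series
        Whitened residuals indexed by date.
    env : DataFrame
        Daily covariates for the same site, with columns date, flux,
        sea_max, night, u (and a, v if requested) and year.

    Returns
    -------
    EnvRegressionFit with the retained terms, coefficients, p-values
    and residuals (indexed by date) of the selected model.
    """
    ev = env.copy()
    ev["date"] = pd.to_datetime(ev["date"])
    ev = ev.set_index("date")
    if lags:
        for lag in range(1, lags + 1):
            for m in DEFAULT_MAIN_EFFECTS:
                ev[f"{m}_lag{lag}"] = ev[m].shift(lag)

    r = resid.copy()
    r.index = pd.to_datetime(r.index)
    data = ev.join(r.rename("resp"), how="inner").dropna()
    multi_year = data["year"].nunique() > 1

    terms = candidate_terms(multi_year, include_extra_wind, lags)
    if len(data) <= len(terms) + 1:
        raise ValueError(
            f"{len(data)} rows cannot support {len(terms)} candidate terms")

    y = data["resp"].to_numpy()
    current = list(terms)
    res = _fit_ols(y, _build_design(current, data))
    best_aic = res.aic
    while True:
        # one backward step: drop the single term whose removal lowers
        # AIC the most, among marginality-respecting removals.  A
        # removal that costs at most AIC_EQUIVALENCE units is also
        # accepted (models within 2 AIC are equivalent; prefer fewer
        # terms), so a term survives only if it clearly earns its place.
        best_step = None
        for t in _removable(current):
            trial = [u for u in current if u != t]
            trial_res = _fit_ols(y, _build_design(trial, data))
            if trial_res.aic <= best_aic + AIC_EQUIVALENCE and (
                    best_step is None or trial_res.aic < best_step[2].aic):
                best_step = (t, trial, trial_res)
        if best_step is None:
            break
        _, current, res = best_step
        best_aic = res.aic

    return EnvRegressionFit(tuple(current), res.params, res.pvalues,
                            float(res.aic),
                            pd.Series(res.resid, index=data.index),
                            nobs=len(data))
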