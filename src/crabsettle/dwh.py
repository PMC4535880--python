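"""Impact inference for the Deepwater Horizon spill.

Two complementary tests of a spill effect on settlement, plus the
statistical power analysis that contextualises their null results:

* a 2x2 factorial ANOVA of site-year mean settlement rates with Site
  (oiled vs reference), Period (before vs after the spill) and their
  interaction as fixed effects — a before-after-control-impact design;
* a one-way ANOVA comparing oiled and not-oiled sites in a single year,
  on log-transformed mean settlement rates or on mean dry weights;
* exact two-sample t-test power over a grid of standardised effect
  sizes (Cohen's d), computed from the noncentral t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Specification of one two-sample t-test power computation."""

    d: float
    n1: int
    n2: int
    alpha: float = 0.05
    sides: int = 2

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.d < 0:
            raise ValueError("effect size must be non-negative")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")


def ttest_power(spec: PowerSpec) -> float:
    """Exact power of the two-sample t-test at effect size d.

    Uses the noncentral t distribution with noncentrality
    lambda = d*sqrt(n1*n2/(n1+n2)) and df = n1+n2-2; two-sided power is
    P(T' > t_crit) + P(T' < -t_crit).
    """
    df = spec.n1 + spec.n2 - 2
    if df < 1:
        raise ValueError("degrees of freedom < 1")
    lam = spec.d * sqrt(spec.n1 * spec.n2 / (spec.n1 + spec.n2))
    if spec.sides == 2:
        t_crit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
        return float(stats.nct.sf(t_crit, df, lam)
                     + stats.nct.cdf(-t_crit, df, lam))
    t_crit = stats.t.ppf(1.0 - spec.alpha, df)
    return float(stats.nct.sf(t_crit, df, lam))


def power_curve(d_grid, n1: int, n2: int, alpha: float = 0.05
                ) -> pd.DataFrame:
    """Power over a grid of effect sizes; monotone non-decreasing in d."""
    d_grid = list(d_grid)
    if not d_grid:
        raise ValueError("empty effect-size grid")
    rows = [{"d": d, "n1": n1, "n2": n2, "alpha": alpha,
             "power": ttest_power(PowerSpec(d, n1, n2, alpha))}
            for d in d_grid]
    return pd.DataFrame(rows)


def _anova_table(res, term_names: dict[str, str]) -> pd.DataFrame:
    raw = sm.stats.anova_lm(res, typ=1)
    raw = raw.rename(index=term_names)
    tab = pd.DataFrame({
        "term": raw.index,
        "df": raw["df"].astype(int).values,
        "sum_sq": raw["sum_sq"].values,
        "mean_sq": (raw["sum_sq"] / raw["df"]).values,
        "F": raw["F"].values,
        "p": raw["PR(>F)"].values,
    }).reset_index(drop=True)
    # constant response: every SS is numerical noise; report F=0, p=1
    scale = float(np.sum(res.model.endog ** 2)) + 1.0
    if tab["sum_sq"].sum() < 1e-12 * scale:
        tab["sum_sq"] = 0.0
        tab["mean_sq"] = 0.0
        is_term = tab["term"] != "Residuals"
        tab.loc[is_term, "F"] = 0.0
        tab.loc[is_term, "p"] = 1.0
    return tab


def factorial_anova(values, site, period) -> pd.DataFrame:
    """2x2 factorial ANOVA (Site, Period, Site:Period) on mean rates.

    Expects a balanced design with >= 2 replicates per cell (site-year
    means serve as replicates).  Returns a type-I ANOVA table with
    columns term, df, sum_sq, mean_sq, F, p and a Residuals row.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "site": list(site), "period": list(period)})
    counts = df.groupby(["site", "period"]).size()
    if df["site"].nunique() != 2 or df["period"].nunique() != 2:
        raise ValueError("factorial design needs two sites and two periods")
    if len(counts) < 4 or (counts < 2).any():
        raise ValueError("each site-period cell needs >= 2 replicates")
    if counts.nunique() != 1:
        raise ValueError("factorial design must be balanced")
    res = smf.ols("y ~ C(site) * C(period)", data=df).fit()
    return _anova_table(res, {
        "C(site)": "Site", "C(period)": "Period",
        "C(site):C(period)": "Site:Period", "Residual": "Residuals"})


def oneway_anova(values, group, log_transform: bool = False
                 ) -> pd.DataFrame:
    """One-way ANOVA of (optionally ln-transformed) values by group."""
    y = np.asarray(values, dtype=float)
    if log_transform:
        if (y <= 0).any():
            raise ValueError(
                "log transform undefined for non-positive values; "
                "apply an offset before calling")
        y = np.log(y)
    df = pd.DataFrame({"y": y, "g": list(group)})
    if df["g"].nunique() < 2:
        raise ValueError("need >= 2 groups")
    if len(df) < 3:
        raise ValueError("need >= 3 observations")
    res = smf.ols("y ~ C(g)", data=df).fit()
    return _anova_table(res, {"C(g)": "Group", "Residual": "Residuals"})
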