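"""Staged decomposition of log settlement variance.

The pipeline follows the standard time-series ordering: fit and remove a
seasonal harmonic trend, then a lunar harmonic trend on the seasonal
residuals (both with AIC selection over Site/Year factorial structures),
then per-site ARIMA whitening, then a per-site environmental regression
on the whitened residuals.  Per site, the variance removed by each stage
is expressed as a fraction of the raw log(rate + 1) variance, giving the
partition seasonal / lunar / autoregressive / environmental /
unexplained that sums to one.

Because the hydrodynamic covariates themselves carry lunar structure,
the point in the sequence at which they enter changes their apparent
explanatory power; :func:`alternate_order_analysis` quantifies this by
fitting the environmental model to the raw data, the seasonal residuals,
the seasonal+lunar residuals and the fully whitened residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arima import ArimaFit, fit_arima_grid
from .envreg import EnvRegressionFit, fit_env_regression
from .harmonics import (HarmonicFit, candidate_structures, delta_aic_table,
                        fit_harmonic, select_model)
from .series import EnvSeries, SettlementSeries

STAGES = ("seasonal", "lunar", "arima", "environmental")


@dataclass(frozen=True)
class VariancePartition:
    """Per-site explained-variance fractions for each stage."""

    site: str
    seasonal: float
    lunar: float
    arima: float
    environmental: float
    unexplained: float

    def __post_init__(self) -> None:
        parts = [self.seasonal, self.lunar, self.arima,
                 self.environmental, self.unexplained]
        total = sum(parts)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")
        if any(p < -1e-12 or p > 1.0 + 1e-12 for p in parts):
            raise ValueError(f"fractions outside [0, 1]: {parts}")

    def as_dict(self) -> dict:
        return {"site": self.site, "seasonal": self.seasonal,
                "lunar": self.lunar, "arima": self.arima,
                "environmental": self.environmental,
                "unexplained": self.unexplained}


def partition_variance(site: str, stage_variances, raw_variance: float
                       ) -> VariancePartition:
    """Turn the chain of residual variances into explained fractions.

    ``stage_variances`` is the sequence of residual variances after each
    stage (seasonal, lunar, arima, environmental), all computed on the
    same site's days; ``raw_variance`` is the variance of the raw
    log-transformed series.  Each stage's share is (variance entering -
    variance leaving) / raw variance; the final residual variance over
    raw variance is the unexplained share.
    """
    if raw_variance <= 0:
        raise ValueError("raw variance must be positive")
    chain = [raw_variance] + list(stage_variances)
    for i, (v_in, v_out) in enumerate(zip(chain, chain[1:])):
        if v_out > v_in + 1e-9 * max(v_in, 1.0):
            raise ValueError(
                f"stage {STAGES[i]} increased variance "
                f"({v_in:.6g} -> {v_out:.6g})")
    shares = [(v_in - v_out) / raw_variance
              for v_in, v_out in zip(chain, chain[1:])]
    shares = [max(s, 0.0) for s in shares]
    unexplained = chain[-1] / raw_variance
    # closure to 1 exactly (clipping can leave sub-1e-9 slack)
    total = sum(shares) + unexplained
    unexplained += 1.0 - total
    return VariancePartition(site, *shares, unexplained)


def partition_table(partitions: list[VariancePartition]) -> pd.DataFrame:
    """Tidy per-site partition table with a cross-site mean row."""
    tab = pd.DataFrame([p.as_dict() for p in partitions])
    mean_row = tab.drop(columns="site").mean()
    mean_row["site"] = "MEAN"
    return pd.concat([tab, mean_row.to_frame().T],
                     ignore_index=True)[tab.columns]


@dataclass
class DecompositionResult:
    """Everything the staged pipeline produces."""

    log_offset: float
    seasonal_fits: list[HarmonicFit]
    seasonal_best: HarmonicFit
    lunar_fits: list[HarmonicFit]
    lunar_best: HarmonicFit
    arima_fits: dict[str, ArimaFit]
    env_fits: dict[str, EnvRegressionFit]
    partitions: list[VariancePartition]
    #: observed rows with log response and stage residuals attached
    frame: pd.DataFrame = field(repr=False)

    def seasonal_aic_table(self) -> pd.DataFrame:
        return delta_aic_table(self.seasonal_fits)

    def lunar_aic_table(self) -> pd.DataFrame:
        return delta_aic_table(self.lunar_fits)

    def partition_frame(self) -> pd.DataFrame:
        return partition_table(self.partitions)


def _var(x) -> float:
    return float(np.var(np.asarray(x, dtype=float), ddof=1))


def _harmonic_stage(y, df, period, terms, cells):
    fits = []
    for structure in candidate_structures(period, terms, cells):
        x = df["day"] if period > 30 else df["lunar_day"]
        fits.append(fit_harmonic(y, structure, x, df["site"], df["year"]))
    return fits, select_model(fits)


def run_decomposition(settlement: SettlementSeries, env: EnvSeries,
                      log_offset: float = 1.0,
                      lunar_terms: tuple[str, ...] = ("sin", "cos", "sincos"),
                      max_order: int = 4, d_max: int = 2,
                      gap_handling: str = "state-space",
                      include_extra_wind: bool = False,
                      env_lags: int = 0) -> DecompositionResult:
    """Run the full staged pipeline on aligned settlement and covariates.

    Stages: log(rate + offset) -> seasonal harmonic (AIC over factorial
    structures) -> lunar harmonic on residuals -> per-site ARIMA ->
    per-site environmental regression -> per-site variance partition.

    The lunar model includes the sin*cos second-harmonic product by
    default; pass ``lunar_terms=("sin", "cos")`` for the additive form.
    """
    obs = settlement.observed().reset_index(drop=True)
    cells = frozenset(settlement.site_years)
    obs["log_rate"] = np.log(obs["rate"].to_numpy(dtype=float) + log_offset)

    seasonal_fits, seasonal_best = _harmonic_stage(
        obs["log_rate"], obs, 365.0, ("sin", "cos"), cells)
    obs["resid_seasonal"] = seasonal_best.residuals

    lunar_fits, lunar_best = _harmonic_stage(
        obs["resid_seasonal"], obs, 30.0, lunar_terms, cells)
    obs["resid_lunar"] = lunar_best.residuals

    arima_fits: dict[str, ArimaFit] = {}
    env_fits: dict[str, EnvRegressionFit] = {}
    partitions: list[VariancePartition] = []
    obs["resid_arima"] = np.nan
    obs["resid_env"] = np.nan

    for site in sorted({s for s, _ in cells}):
        mask = obs["site"] == site
        sub = obs[mask]
        resid = pd.Series(sub["resid_lunar"].to_numpy(),
                          index=pd.to_datetime(sub["date"]))
        afit = fit_arima_grid(resid, max_order=max_order, d_max=d_max,
                              gap_handling=gap_handling)
        arima_fits[site] = afit
        white = afit.resid
        obs.loc[mask, "resid_arima"] = white.reindex(
            pd.to_datetime(sub["date"])).to_numpy()

        efit = fit_env_regression(white, env.site(site),
                                  include_extra_wind=include_extra_wind,
                                  lags=env_lags)
        env_fits[site] = efit
        obs.loc[mask, "resid_env"] = efit.resid.reindex(
            pd.to_datetime(sub["date"])).to_numpy()

        # variances per site over the days present at each stage
        raw_var = _var(sub["log_rate"])
        v_seasonal = _var(sub["resid_seasonal"])
        v_lunar = _var(sub["resid_lunar"])
        v_arima = _var(white.dropna())
        v_env = _var(efit.resid)
        partitions.append(partition_variance(
            site, [v_seasonal, v_lunar, v_arima, v_env], raw_var))

    return DecompositionResult(log_offset, seasonal_fits, seasonal_best,
                               lunar_fits, lunar_best, arima_fits,
                               env_fits, partitions, obs)


ENTRY_POINTS = ("raw", "post_seasonal", "post_lunar", "post_arima")


def alternate_order_analysis(settlement: SettlementSeries, env: EnvSeries,
                             result: DecompositionResult | None = None,
                             **kwargs) -> pd.DataFrame:
    """Environmental explanatory power at four pipeline entry points.

    Fits the environmental regression to (a) the raw log data, (b) the
    seasonal residuals, (c) the seasonal+lunar residuals and (d) the
    fully whitened residuals (the primary ordering), per site.  The
    explained share is reported relative to the raw log-series variance
    throughout, so rows are directly comparable.
    """
    if result is None:
        result = run_decomposition(settlement, env, **kwargs)
    obs = result.frame
    response_cols = {"raw": "log_rate", "post_seasonal": "resid_seasonal",
                     "post_lunar": "resid_lunar", "post_arima": None}
    rows = []
    for site in sorted(obs["site"].unique()):
        sub = obs[obs["site"] == site]
        raw_var = _var(sub["log_rate"])
        for entry in ENTRY_POINTS:
            if entry == "post_arima":
                efit = result.env_fits[site]
                v_in = _var(result.arima_fits[site].resid.dropna())
            else:
                col = response_cols[entry]
                resp = pd.Series(sub[col].to_numpy(),
                                 index=pd.to_datetime(sub["date"]))
                efit = fit_env_regression(resp, env.site(site))
                v_in = _var(resp)
            v_out = _var(efit.resid)
            rows.append({"site": site, "entry": entry,
                         "explained_share": (v_in - v_out) / raw_var})
    tab = pd.DataFrame(rows)
    means = (tab.groupby("entry", sort=False)["explained_share"]
             .mean().reset_index())
    means.insert(0, "site", "MEAN")
    return pd.concat([tab, means], ignore_index=True)
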