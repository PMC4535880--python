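"""ARIMA whitening of harmonic residuals by AIC grid search.

Residual series from the lunar stage retain short-range autocorrelation.
Each site's residuals are placed on a continuous daily index (weekend
sampling gaps become missing observations, handled by the state-space
likelihood) and ARIMA(p, d, q) models are fit over a grid of orders.
The minimum-AIC convergent fit is selected, with the same parsimony
rule used for the harmonic models: candidates within 2 AIC units of the
best are equivalent, and the one with fewest estimated parameters wins.
Differencing is searched over 0..2 by default; orders up to 4 in every
component are allowed but d > 2 on season-length series is numerically
fragile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.arima.model import ARIMA

from .harmonics import AIC_EQUIVALENCE


@dataclass
class ArimaFit:
    """Selected ARIMA model and its whitened residuals."""

    order: tuple[int, int, int]
    params: pd.Series
    aic: float
    n_params: int
    #: one-step-ahead prediction residuals at observed time points
    resid: pd.Series = field(repr=False)
    aic_table: pd.DataFrame = field(repr=False)

    @property
    def ar_coef(self) -> float:
        """First autoregressive coefficient, 0.0 if the model has none."""
        for name, val in self.params.items():
            if name.startswith("ar.L1"):
                return float(val)
        return 0.0


def _daily_index_series(resid: pd.Series) -> pd.Series:
    """Place a date-indexed series on a continuous daily index, NaN on
    unsampled days."""
    s = resid.copy()
    s.index = pd.to_datetime(s.index)
    full = pd.date_range(s.index.min(), s.index.max(), freq="D")
    return s.reindex(full)


def fit_arima_grid(resid: pd.Series, max_order: int = 4,
                   d_max: int = 2, gap_handling: str = "state-space"
                   ) -> ArimaFit:
    """Grid-search ARIMA orders on a date-indexed residual series.

    Parameters
    ----------
    resid : Series
        Residuals indexed by date (only sampled days present).
    max_order : int
        Maximum AR and MA order searched (0..max_order).
    d_max : int
        Maximum differencing order searched (0..min(d_max, 4)).
    gap_handling : {"state-space", "concatenate"}
        "state-space" treats weekly gaps as missing observations on a
        continuous daily index; "concatenate" simply joins the sampled
        days end to end.

    Returns
    -------
    ArimaFit for the selected order, with one-step-ahead residuals at
    the observed dates and the full AIC table of convergent candidates.
    """
    if len(resid) < 50:
        raise ValueError(f"need >= 50 observations, got {len(resid)}")
    if gap_handling == "state-space":
        y = _daily_index_series(resid)
    elif gap_handling == "concatenate":
        y = pd.Series(resid.to_numpy(),
                      index=pd.RangeIndex(len(resid)))
    else:
        raise ValueError(f"unknown gap_handling {gap_handling!r}")

    observed_mask = y.notna()
    input_var = float(y.var(ddof=1))
    candidates = []
    rows = []
    for d in range(min(d_max, 4) + 1):
        for p in range(max_order + 1):
            for q in range(max_order + 1):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        res = ARIMA(y.to_numpy(), order=(p, d, q),
                                    enforce_stationarity=True,
                                    enforce_invertibility=True,
                                    ).fit(method_kwargs={"maxiter": 200})
                    except (np.linalg.LinAlgError, ValueError):
                        continue
                if not np.isfinite(res.aic):
                    continue
                # residual sanity check, the automated analogue of
                # visual residual inspection: a usable whitening model
                # must not inflate the variance of the series (heavily
                # differenced fits can produce explosive one-step
                # predictions around sampling gaps)
                white = res.resid.copy()
                white[:d] = np.nan
                wvar = float(np.nanvar(white[observed_mask], ddof=1))
                if not np.isfinite(wvar) or wvar > input_var * (1 + 1e-9):
                    continue
                candidates.append(((p, d, q), res))
                rows.append({"p": p, "d": d, "q": q,
                             "n_params": len(res.params),
                             "aic": float(res.aic)})
    if not candidates:
        raise RuntimeError("no ARIMA candidate converged")

    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    best_aic = table["aic"].min()
    equiv = [(o, r) for o, r in candidates
             if r.aic - best_aic <= AIC_EQUIVALENCE]
    order, res = min(equiv, key=lambda c: (len(c[1].params), c[1].aic))

    resid_vals = res.resid.copy()
    resid_vals[:order[1]] = np.nan  # differencing burn-in
    resid_full = pd.Series(resid_vals, index=y.index)
    white = resid_full[observed_mask]
    names = res.model.param_names if hasattr(res.model, "param_names") \
        else [f"p{i}" for i in range(len(res.params))]
    return ArimaFit(order, pd.Series(res.params, index=names),
                    float(res.aic), len(res.params), white, table)
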