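"""Harmonic design expansion, parameter counting, fitting and selection."""

import math

import numpy as np
import pandas as pd
import pytest

from crabsettle.harmonics import (HarmonicFit, HarmonicStructure,
                                  candidate_structures, count_parameters,
                                  design_matrix, fit_harmonic,
                                  gaussian_loglik, peak_day, select_model)

SEASONAL_KS = {"full": 28, "site": 16, "year": 7, "plain": 4, "null": 2}
LUNAR_KS = {"full": 37, "site": 21, "year": 9, "plain": 5, "null": 2}


class TestCountParameters:
    def test_unbalanced_five_site_design(self, study_cells):
        """Full factorial crossing with one absent site-year cell."""
        seasonal = candidate_structures(365.0, ("sin", "cos"), study_cells)
        assert {s.name: count_parameters(s) for s in seasonal} == SEASONAL_KS
        lunar = candidate_structures(30.0, ("sin", "cos", "sincos"),
                                     study_cells)
        assert {s.name: count_parameters(s) for s in lunar} == LUNAR_KS

    def test_balanced_design_has_no_dropping(self):
        cells = frozenset((s, y) for s in "ABCDE" for y in (1, 2))
        full = HarmonicStructure(365.0, ("sin", "cos"), ("Site", "Year"),
                                 cells, "full")
        # 10 intercept-block + 2*10 harmonic columns, + variance
        assert count_parameters(full) == 31

    def test_empty_design_rejected(self):
        s = HarmonicStructure(365.0, ("sin", "cos"), (), frozenset(), "x")
        with pytest.raises(ValueError):
            count_parameters(s)


def _plain_data(n=200, seed=0, a=2.0, b=3.0, noise=0.0):
    rng = np.random.default_rng(seed)
    day = rng.integers(1, 366, size=n)
    ang = 2 * math.pi * day / 365.0
    y = a * np.sin(ang) + b * np.cos(ang) + noise * rng.normal(size=n)
    site = np.repeat("A", n)
    year = np.repeat(2010, n)
    return y, day, site, year


class TestFitHarmonic:
    def test_noiseless_recovery(self):
        y, day, site, year = _plain_data()
        s = HarmonicStructure(365.0, ("sin", "cos"), (),
                              frozenset({("A", 2010)}), "plain")
        fit = fit_harmonic(y, s, day, site, year)
        assert fit.coefficients["sin"] == pytest.approx(2.0, abs=1e-9)
        assert fit.coefficients["cos"] == pytest.approx(3.0, abs=1e-9)
        assert np.var(fit.residuals) == pytest.approx(0.0, abs=1e-18)

    def test_aic_matches_closed_form_loglik(self):
        """AIC equals 2k - 2*logLik with the Gaussian ML likelihood
        recomputed independently from the residuals."""
        y, day, site, year = _plain_data(noise=0.5, seed=3)
        s = HarmonicStructure(365.0, ("sin", "cos"), (),
                              frozenset({("A", 2010)}), "plain")
        fit = fit_harmonic(y, s, day, site, year)
        resid = fit.residuals
        n = len(resid)
        sigma2 = float(resid @ resid) / n
        ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
        assert fit.loglik == pytest.approx(ll, rel=1e-12)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * ll, rel=1e-12)

    def test_ols_equals_normal_equations_oracle(self):
        """Coefficients equal the textbook (X'X)^-1 X'y solution on an
        independently constructed design."""
        y, day, site, year = _plain_data(noise=1.0, seed=7)
        s = HarmonicStructure(365.0, ("sin", "cos"), (),
                              frozenset({("A", 2010)}), "plain")
        fit = fit_harmonic(y, s, day, site, year)
        ang = 2 * math.pi * np.asarray(day) / 365.0
        X = np.column_stack([np.ones_like(ang), np.sin(ang), np.cos(ang)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        ours = fit.coefficients[["1", "sin", "cos"]].to_numpy()
        assert np.max(np.abs(ours - beta)) < 1e-8

    def test_single_site_full_equals_site_structure(self):
        y, day, site, year = _plain_data(noise=0.3, seed=1)
        cells = frozenset({("A", 2010)})
        fits = {}
        for name, factors in (("site", ("Site",)), ("full", ("Site", "Year"))):
            s = HarmonicStructure(365.0, ("sin", "cos"), factors, cells, name)
            fits[name] = fit_harmonic(y, s, day, site, year)
        assert fits["site"].k == fits["full"].k
        assert fits["site"].aic == pytest.approx(fits["full"].aic)
        assert np.allclose(fits["site"].residuals, fits["full"].residuals)

    def test_rank_deficiency_reported(self):
        # two sites in the structure but only one in the data rows
        y, day, site, year = _plain_data()
        cells = frozenset({("A", 2010), ("B", 2010)})
        s = HarmonicStructure(365.0, ("sin", "cos"), ("Site",), cells, "site")
        with pytest.raises(ValueError, match="rank"):
            fit_harmonic(y, s, day, site, year)

    def test_missing_values_rejected(self):
        y, day, site, year = _plain_data()
        y = y.copy()
        y[0] = np.nan
        s = HarmonicStructure(365.0, ("sin", "cos"), (),
                              frozenset({("A", 2010)}), "plain")
        with pytest.raises(ValueError, match="missing"):
            fit_harmonic(y, s, day, site, year)


def _dummy_fit(aic, k, name="m"):
    s = HarmonicStructure(365.0, ("sin", "cos"), (),
                          frozenset({("A", 2010)}), name)
    return HarmonicFit(s, pd.Series(dtype=float), k, 0.0, aic,
                       np.zeros(3))


class TestSelectModel:
    def test_equivalence_prefers_fewer_parameters(self):
        full = _dummy_fit(3769.3, 28, "full")
        site = _dummy_fit(3769.4, 16, "site")
        assert select_model([full, site]).name == "site"

    def test_clear_winner_kept_despite_complexity(self):
        assert select_model([_dummy_fit(100.0, 5, "big"),
                             _dummy_fit(150.0, 3, "small")]).name == "big"

    def test_single_candidate(self):
        f = _dummy_fit(10.0, 2)
        assert select_model([f]) is f

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_model([])


class TestPeakDay:
    def _fit(self, a, b, period=365.0):
        n = 400
        rng = np.random.default_rng(0)
        x = rng.uniform(1, period, size=n)
        ang = 2 * math.pi * x / period
        y = a * np.sin(ang) + b * np.cos(ang)
        s = HarmonicStructure(period, ("sin", "cos"), (),
                              frozenset({("A", 2010)}), "plain")
        return fit_harmonic(y, s, x, np.repeat("A", n), np.repeat(2010, n))

    def test_pure_sine_peaks_at_quarter_period(self):
        assert peak_day(self._fit(1.0, 0.0), "A") == pytest.approx(
            365.0 / 4, abs=0.01)

    def test_pure_cosine_peaks_at_zero(self):
        assert peak_day(self._fit(0.0, 1.0), "A") == pytest.approx(0.0,
                                                                   abs=0.01)

    def test_mixed_peak_matches_grid_oracle(self):
        fit = self._fit(1.0, 1.0)
        grid = np.arange(0, 365, 0.001)
        curve = np.sin(2 * math.pi * grid / 365) + np.cos(
            2 * math.pi * grid / 365)
        oracle = grid[np.argmax(curve)]
        assert peak_day(fit, "A") == pytest.approx(oracle, abs=0.01)
        assert oracle == pytest.approx(45.625, abs=0.001)

    def test_lunar_peak_in_lunar_days(self):
        fit = self._fit(1.0, 0.0, period=30.0)
        peak = peak_day(fit, "A")
        assert 1.0 <= peak < 31.0
        assert peak == pytest.approx(30.0 / 4 + 0, abs=0.51)

    def test_flat_curve_rejected(self):
        fit = self._fit(1.0, 0.0)
        fit.coefficients[:] = 0.0
        with pytest.raises(ValueError, match="flat"):
            peak_day(fit, "A")


def test_design_matrix_drops_absent_cell_columns(study_cells):
    """The data design matrix for the unbalanced study design has full
    column rank and exactly k-1 columns."""
    rng = np.random.default_rng(2)
    rows = []
    for s, y in sorted(study_cells):
        for d in rng.integers(130, 300, size=12):
            rows.append((s, y, int(d)))
    site = np.array([r[0] for r in rows])
    year = np.array([r[1] for r in rows])
    day = np.array([r[2] for r in rows])
    full = HarmonicStructure(365.0, ("sin", "cos"), ("Site", "Year"),
                             study_cells, "full")
    X, names = design_matrix(full, day, site, year)
    assert X.shape[1] == count_parameters(full) - 1 == 27
    assert np.linalg.matrix_rank(X) == X.shape[1]
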