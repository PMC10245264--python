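"""Contribution series, trend statistics and driver classification."""

import numpy as np
import pytest

from lwlr_attrib import (
    CellSeries,
    KernelSpec,
    SyntheticTruth,
    CoefficientFunction,
    ClimateParams,
    make_cell,
    fit_lwlr,
    pnc_series,
    apnc,
    stl_trend,
    cubic_mean_trend,
    compute_alphas,
    ingredient_structure,
    relative_roles,
    apnc_share,
    monthly_slope_class,
    attribute,
)
from lwlr_attrib.lwlr_core import LWLRFit
from tests.conftest import CONST_BETA


def _fit_from_beta(beta_t, cell):
    """Wrap an arbitrary coefficient trajectory as an LWLRFit for testing."""
    from lwlr_attrib.lwlr_core import build_design

    X = build_design(cell.temp, cell.precip)
    fitted = np.einsum("ti,ti->t", X, beta_t)
    m = cell.n_months
    return LWLRFit(beta_t=beta_t, fitted=fitted, residuals=cell.ndvi - fitted,
                   rl2=1.0, rg2=1.0, rlg=1.0, kernel=KernelSpec(6, 6),
                   boundary_flag=np.zeros(m, bool), singular_flag=np.zeros(m, bool))


class TestPncSeries:
    def test_hand_case(self, exact_cell):
        m = exact_cell.n_months
        beta_t = np.tile([0.1, 0.02, 0.0, 0.001, 0.0], (m, 1))
        cell = CellSeries("h", 0, 0, exact_cell.ndvi,
                          np.full(m, 10.0), np.full(m, 50.0))
        series = pnc_series(_fit_from_beta(beta_t, cell), cell)
        assert series.f_hat[0] == pytest.approx(0.2)
        assert series.g_hat[0] == pytest.approx(0.05)
        assert series.b0_hat[0] == pytest.approx(0.1)

    def test_zero_climate_coefficients_zero_f(self, exact_cell):
        m = exact_cell.n_months
        beta_t = np.tile([0.3, 0.0, 0.0, 0.001, 0.0], (m, 1))
        series = pnc_series(_fit_from_beta(beta_t, exact_cell), exact_cell)
        np.testing.assert_allclose(series.f_hat, 0.0, atol=1e-15)

    def test_additive_identity(self, noisy_cell):
        fit = fit_lwlr(noisy_cell, KernelSpec(6, 9))
        series = pnc_series(fit, noisy_cell)
        total = series.f_hat + series.g_hat + series.b0_hat
        np.testing.assert_allclose(total, fit.fitted, atol=1e-12)


class TestApnc:
    def test_means_and_tie_flag(self, exact_cell):
        m = exact_cell.n_months
        beta_t = np.tile([0.5, 0.0, 0.0, 0.0, 0.0], (m, 1))
        cell = CellSeries("t", 0, 0, exact_cell.ndvi,
                          np.full(m, 1.0), np.full(m, 1.0))
        # f = g = 0.25 with unit climate, so climate total exactly equals b0
        beta_t[:, 1] = 0.25
        beta_t[:, 3] = 0.25
        series = pnc_series(_fit_from_beta(beta_t, cell), cell)
        f, g, b0, dominant = apnc(series)
        assert (f, g, b0) == (pytest.approx(0.25), pytest.approx(0.25), pytest.approx(0.5))
        assert dominant == "tie"

    def test_linearity_of_means(self, noisy_cell):
        fit = fit_lwlr(noisy_cell, KernelSpec(9, 9))
        series = pnc_series(fit, noisy_cell)
        f, g, b0, _ = apnc(series)
        assert f + g + b0 == pytest.approx(float(fit.fitted.mean()), abs=1e-12)

    def test_negative_climate_reported(self, exact_cell):
        m = exact_cell.n_months
        beta_t = np.tile([0.3, -0.1, 0.0, 0.0, 0.0], (m, 1))
        cell = CellSeries("n", 0, 0, exact_cell.ndvi, np.ones(m), np.ones(m))
        series = pnc_series(_fit_from_beta(beta_t, cell), cell)
        f, g, b0, dominant = apnc(series)
        assert f + g < 0
        assert dominant == "anthropogenic"


class TestStlTrend:
    def test_component_sum_reconstructs(self, rng):
        from statsmodels.tsa.seasonal import STL

        x = rng.normal(size=120) + np.sin(np.arange(120) * 2 * np.pi / 12)
        res = STL(x, period=12, seasonal=13, robust=True).fit()
        np.testing.assert_allclose(res.trend + res.seasonal + res.resid, x, atol=1e-10)

    def test_pure_sinusoid_has_flat_trend(self):
        t = np.arange(240)
        x = 0.8 * np.sin(2 * np.pi * t / 12)
        trend = stl_trend(x)
        interior = slice(12, -12)
        assert np.max(np.abs(trend[interior])) < 0.05 * 0.8

    def test_linear_ramp_recovered(self):
        t = np.arange(1, 241, dtype=float)
        x = 0.2 + 0.001 * t
        trend = stl_trend(x)
        interior = slice(12, -12)
        np.testing.assert_allclose(trend[interior], x[interior], rtol=0.01)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="two periods"):
            stl_trend(np.ones(20))


class TestCubicMeanTrend:
    def test_linear_series(self):
        t = np.arange(1, 121, dtype=float)
        fit = cubic_mean_trend(3 + 0.5 * t)
        assert fit.mean_derivative == pytest.approx(0.5, rel=1e-9)

    def test_constant_series(self):
        assert cubic_mean_trend(np.full(60, 2.5)).mean_derivative == pytest.approx(0.0, abs=1e-10)

    def test_pure_cubic_closed_form(self):
        """series = t^3 on 24 months: mean derivative = (1/24) sum 3t^2 = 612.5,
        and agrees with numerical differentiation of the fitted cubic."""
        t = np.arange(1, 25, dtype=float)
        fit = cubic_mean_trend(t ** 3)
        assert fit.mean_derivative == pytest.approx(612.5, rel=1e-9)
        c = fit.coefficients
        grid = np.linspace(1, 24, 4001)
        poly = c[0] + c[1] * grid + c[2] * grid ** 2 + c[3] * grid ** 3
        numeric = np.trapezoid(np.gradient(poly, grid), grid) / 23.0
        # integral mean of the derivative over [1, 24] is close to the
        # discrete month-mean for a smooth cubic
        assert numeric == pytest.approx(fit.mean_derivative, rel=0.05)

    def test_residuals_stored(self, rng):
        y = rng.normal(size=100)
        fit = cubic_mean_trend(y)
        np.testing.assert_allclose(fit.fitted + fit.residuals, y, atol=1e-10)


class TestComputeAlphas:
    def test_rising_climate_trend_gives_positive_alpha(self):
        """Warming temperature through a positive coefficient raises the
        climate contribution trend, so alpha > 0."""
        temp = ClimateParams(mean=10.0, seasonal_amplitude=12.0, slope=0.02,
                             phase=7.0, rho=0.3, sigma=1.0)
        truth = SyntheticTruth(beta=CONST_BETA, temp=temp, noise_sigma=0.005, seed=21)
        cell = make_cell(truth, 240)
        fit = fit_lwlr(cell, KernelSpec(12, 12))
        series = pnc_series(fit, cell)
        alpha, alpha0, _, _ = compute_alphas(series, fit)
        assert alpha > 0

    def test_rising_intercept_recovered(self):
        """alpha0 recovers the generating intercept slope within 25%."""
        vals = []
        for seed in range(15):
            beta = (CoefficientFunction("linear", c0=0.20, slope=5e-4),) + CONST_BETA[1:]
            truth = SyntheticTruth(beta=beta, noise_sigma=0.01, seed=1200 + seed)
            cell = make_cell(truth, 240)
            fit = fit_lwlr(cell, KernelSpec(12, 12))
            vals.append(compute_alphas(pnc_series(fit, cell), fit)[1])
        assert np.mean(vals) == pytest.approx(5e-4, rel=0.25)


class TestIngredientStructure:
    def test_constant_coefficients_linear_climate(self):
        """With constant b1, b3 and exactly linear T, P the derivative terms
        vanish and the mean reduces to b1*slope_T + b3*slope_P."""
        m = 120
        t = np.arange(1, m + 1, dtype=float)
        sT, sP = 0.01, 0.05
        cell = CellSeries("lin", 0, 0, np.full(m, 0.5), 5 + sT * t, 40 + sP * t)
        beta_t = np.tile([0.2, 0.01, 0.0, 0.001, 0.0], (m, 1))
        result = ingredient_structure(_fit_from_beta(beta_t, cell), cell)
        assert result["approx_mean"] == pytest.approx(0.01 * sT + 0.001 * sP, rel=1e-6)

    def test_temperature_only_model_labelled(self, exact_cell):
        m = exact_cell.n_months
        beta_t = np.tile([0.2, 0.01, 0.0, 0.0, 0.0], (m, 1))
        result = ingredient_structure(_fit_from_beta(beta_t, exact_cell), exact_cell)
        assert result["dominant_factor"] == "temperature"

    def test_approximation_tracks_full_derivative(self):
        """With small quadratic generating terms the first-order decomposition
        approximates the numerical derivative of the climate-trend curve."""
        beta = (CONST_BETA[0],
                CoefficientFunction("linear", c0=0.01, slope=1e-5),
                CoefficientFunction("constant", c0=-1e-6),
                CONST_BETA[3],
                CoefficientFunction("constant", c0=-1e-8))
        temp = ClimateParams(mean=10.0, seasonal_amplitude=12.0, slope=0.01,
                             phase=7.0, rho=0.3, sigma=1.0)
        truth = SyntheticTruth(beta=beta, temp=temp, noise_sigma=0.003, seed=77)
        cell = make_cell(truth, 240)
        fit = fit_lwlr(cell, KernelSpec(12, 12))
        series = pnc_series(fit, cell)
        full = float(np.mean(np.gradient(series.fg_trend)))
        approx = ingredient_structure(fit, cell)["approx_mean"]
        assert approx == pytest.approx(full, rel=0.5)


class TestRelativeRoles:
    @pytest.mark.parametrize(
        "alpha0, alpha, ra, rc",
        [
            (3e-6, 1e-6, 0.75, 0.25),
            (2e-6, 2e-6, 0.5, 0.5),
            (-1e-6, 2e-6, -1.0, 2.0),
        ],
    )
    def test_printed_formula(self, alpha0, alpha, ra, rc):
        got_ra, got_rc, defined, _ = relative_roles(alpha0, alpha)
        assert defined
        assert got_ra == pytest.approx(ra)
        assert got_rc == pytest.approx(rc)

    def test_ra_rc_sum_to_one_whenever_defined(self, rng):
        for _ in range(100):
            a0, a = rng.normal(scale=1e-4, size=2)
            ra, rc, defined, _ = relative_roles(a0, a)
            if defined:
                assert ra + rc == pytest.approx(1.0, abs=1e-9)

    def test_undefined_flag_near_cancellation(self):
        ra, rc, defined, _ = relative_roles(1e-13, -1e-13)
        assert not defined
        assert np.isnan(ra) and np.isnan(rc)

    def test_driver_classes(self):
        assert relative_roles(1e-5, 1e-5)[3] == "both promote"
        assert relative_roles(1e-5, -1e-5)[3] == "anthropogenic promotes, climate degrades"
        assert relative_roles(-1e-5, 1e-5)[3] == "climate promotes, anthropogenic degrades"
        assert relative_roles(-1e-5, -1e-5)[3] == "both degrade"
        assert relative_roles(1e-9, 1e-9)[3] == "no significant trend"


class TestApncShare:
    @pytest.mark.parametrize(
        "f_g, b0, expected, bin_",
        [
            (0.3, 0.3, 0.5, "<=0.5"),
            (0.1, 0.3, 0.75, "0.51-0.75"),
            (-0.1, 0.3, 1.5, ">1"),
        ],
    )
    def test_printed_formula_and_bins(self, f_g, b0, expected, bin_):
        r, b, defined = apnc_share(f_g, 0.0, b0)
        assert defined
        assert r == pytest.approx(expected)
        assert b == bin_

    def test_undefined_denominator(self):
        r, b, defined = apnc_share(0.15, -0.15, 0.0)
        assert not defined and b == "undefined"


class TestMonthlySlopeClass:
    def _cell_with_trend(self, slope, m=240):
        t = np.arange(1, m + 1, dtype=float)
        season = 0.05 * np.sin(2 * np.pi * t / 12)
        return 0.4 + slope * t + season

    @pytest.mark.parametrize(
        "slope, expected",
        [
            (3e-5, "promoted"),
            (0.0, "non-significant"),
            (3e-4, "strongly-promoted"),
            (-1e-4, "degraded"),
        ],
    )
    def test_threshold_classes(self, slope, expected):
        got_slope, cls = monthly_slope_class(self._cell_with_trend(slope))
        assert cls == expected
        assert got_slope == pytest.approx(slope, abs=5e-6)


class TestScaleConsistency:
    def test_ndvi_rescaling_scales_levels_not_ratios(self, noisy_cell):
        """Multiplying NDVI by c scales the APNC values and alphas by c and
        leaves Ra, Rc and R_ac unchanged."""
        c = 3.0
        scaled = CellSeries("s", 0, 0, c * noisy_cell.ndvi,
                            noisy_cell.temp, noisy_cell.precip)
        spec = KernelSpec(9, 9)
        a1 = attribute(fit_lwlr(noisy_cell, spec), noisy_cell)
        a2 = attribute(fit_lwlr(scaled, spec), scaled)
        for name in ("f_bar", "g_bar", "b0_bar", "alpha", "alpha0"):
            assert getattr(a2, name) == pytest.approx(c * getattr(a1, name), rel=1e-6, abs=1e-12)
        for name in ("ra", "rc", "r_ac"):
            assert getattr(a2, name) == pytest.approx(getattr(a1, name), rel=1e-6)
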