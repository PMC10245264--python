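"""From coefficient trajectories to climate / anthropogenic attribution.

The fitted local model splits NDVI additively into three predicted
nonlinear contributions (PNC):

* temperature: ``f(t) = b1(t) T(t) + b2(t) T^2(t)``
* precipitation: ``g(t) = b3(t) P(t) + b4(t) P^2(t)``
* anthropogenic: the time-varying intercept ``b0(t)``

Their time means (APNC) measure each driver's average level.  Trends are
measured as *average changing trends*: the climate contribution
``f + g`` is first STL-detrended to remove the seasonal cycle, the
resulting trend curve (and ``b0(t)`` directly) is fitted by a cubic in
``t``, and the mean of the cubic's first derivative over the record is
the trend statistic (``alpha`` for climate, ``alpha0`` for
anthropogenic).  The ratio ``Ra = alpha0 / (alpha0 + alpha)`` and its
complement ``Rc = 1 - Ra`` apportion the NDVI dynamic between the two
driver groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.tsa.seasonal import STL

from .lwlr_core import CellSeries, LWLRFit

__all__ = [
    "ALPHA_SIG", "SLOPE_THRESH", "SLOPE_EXTREME",
    "ContributionSeries", "CubicFit", "AttributionResult",
    "pnc_series", "apnc", "stl_trend", "cubic_mean_trend",
    "compute_alphas", "ingredient_structure", "relative_roles",
    "apnc_share", "monthly_slope_class", "attribute",
]

#: |alpha| below this (NDVI units per month) is treated as insignificant
#: when classifying driver roles.
ALPHA_SIG = 5e-6

#: Monthly NDVI-trend slope thresholds: |slope| <= SLOPE_THRESH is
#: "non-significant"; slope > SLOPE_EXTREME is "strongly promoted".
SLOPE_THRESH = 2e-5
SLOPE_EXTREME = 2e-4

#: STL settings used throughout: monthly period, robust loess, seasonal
#: smoother window 13.
STL_KWARGS = dict(period=12, seasonal=13, robust=True)


@dataclass
class ContributionSeries:
    """Per-month predicted nonlinear contributions of the three drivers."""

    f_hat: np.ndarray           # temperature PNC
    g_hat: np.ndarray           # precipitation PNC
    b0_hat: np.ndarray          # anthropogenic PNC (time-varying intercept)
    fg: np.ndarray              # climate PNC, f_hat + g_hat
    fg_trend: np.ndarray        # STL trend component of fg


@dataclass
class CubicFit:
    """Cubic-in-time OLS fit and the mean of its first derivative."""

    coefficients: np.ndarray    # [c0, c1, c2, c3] on the raw month index t
    fitted: np.ndarray
    residuals: np.ndarray
    mean_derivative: float      # (1/M) sum_t (3 c3 t^2 + 2 c2 t + c1)


@dataclass
class AttributionResult:
    """Complete per-cell attribution summary."""

    f_bar: float
    g_bar: float
    b0_bar: float
    climate_bar: float              # f_bar + g_bar
    dominant_apnc: str              # "climate" | "anthropogenic" | "tie"
    alpha: float                    # mean changing trend of the climate PNC trend curve
    alpha0: float                   # mean changing trend of b0(t)
    alpha1: float                   # mean changing trend of b1(t)
    alpha3: float                   # mean changing trend of b3(t)
    ra: float                       # anthropogenic relative contribution ratio
    rc: float                       # climate relative contribution ratio
    ratio_defined: bool
    driver_class: str
    r_ac: float                     # APNC share of anthropogenic activity
    r_ac_bin: str
    r_ac_defined: bool
    ingredient: dict = field(default_factory=dict)
    dominant_factor: str = ""


def pnc_series(fit: LWLRFit, cell: CellSeries) -> ContributionSeries:
    """Split the fitted NDVI into temperature, precipitation and intercept parts.

    The three series sum to the fitted NDVI at every month by
    construction of the additive model.
    """
    m = fit.n_months
    if m != cell.n_months:
        raise ValueError(f"fit covers {m} months but cell has {cell.n_months}")
    b = fit.beta_t
    T, P = cell.temp, cell.precip
    f_hat = b[:, 1] * T + b[:, 2] * T ** 2
    g_hat = b[:, 3] * P + b[:, 4] * P ** 2
    b0_hat = b[:, 0]
    fg = f_hat + g_hat
    return ContributionSeries(f_hat=f_hat, g_hat=g_hat, b0_hat=b0_hat,
                              fg=fg, fg_trend=stl_trend(fg))


def apnc(series: ContributionSeries) -> tuple[float, float, float, str]:
    """Time-mean contributions and the dominant driver group.

    Returns ``(f_bar, g_bar, b0_bar, dominant)`` where ``dominant`` is
    ``"climate"`` when ``f_bar + g_bar > b0_bar``, ``"anthropogenic"``
    when smaller, and ``"tie"`` at exact equality.
    """
    f_bar = float(series.f_hat.mean())
    g_bar = float(series.g_hat.mean())
    b0_bar = float(series.b0_hat.mean())
    climate = f_bar + g_bar
    if climate > b0_bar:
        dominant = "climate"
    elif climate < b0_bar:
        dominant = "anthropogenic"
    else:
        dominant = "tie"
    return f_bar, g_bar, b0_bar, dominant


def stl_trend(series: np.ndarray, period: int = 12) -> np.ndarray:
    """Trend component of a robust STL decomposition (monthly period)."""
    x = np.asarray(series, dtype=float)
    if x.size < 2 * period:
        raise ValueError(f"need at least two periods ({2 * period} months), got {x.size}")
    kwargs = dict(STL_KWARGS)
    kwargs["period"] = period
    res = STL(x, **kwargs).fit()
    return np.asarray(res.trend)


def cubic_mean_trend(series: np.ndarray) -> CubicFit:
    """OLS cubic fit in the month index and the mean of its derivative.

    The month index is rescaled to [0, 1] inside the solver for
    conditioning; coefficients and the derivative are reported on the
    raw ``t = 1..M`` scale.  The mean derivative is the closed form
    ``(1/M) sum_t (3 c3 t^2 + 2 c2 t + c1)``.
    """
    y = np.asarray(series, dtype=float)
    m = y.size
    if m < 8:
        raise ValueError("need at least 8 points for a stable cubic fit")
    t = np.arange(1, m + 1, dtype=float)
    s = t / m                                   # rescaled regressor
    Xs = np.vander(s, 4, increasing=True)       # [1, s, s^2, s^3]
    c_s, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    # map coefficients back to the raw t scale: s = t/m
    scale = np.array([1.0, 1 / m, 1 / m ** 2, 1 / m ** 3])
    c = c_s * scale                             # [c0, c1, c2, c3] in t
    fitted = Xs @ c_s
    deriv = 3 * c[3] * t ** 2 + 2 * c[2] * t + c[1]
    return CubicFit(coefficients=c, fitted=fitted, residuals=y - fitted,
                    mean_derivative=float(deriv.mean()))


def compute_alphas(
    series: ContributionSeries, fit: LWLRFit
) -> tuple[float, float, float, float]:
    """Average changing trends of the contribution and coefficient series.

    ``alpha`` is the mean derivative of a cubic fitted to the STL trend
    of the climate contribution; ``alpha0``, ``alpha1`` and ``alpha3``
    come from cubics fitted directly to the ``b0``, ``b1`` and ``b3``
    trajectories (the intercept and linear climate coefficients carry no
    seasonal cycle of their own, so no STL is applied to them).
    """
    alpha = cubic_mean_trend(series.fg_trend).mean_derivative
    alpha0 = cubic_mean_trend(series.b0_hat).mean_derivative
    alpha1 = cubic_mean_trend(fit.beta_t[:, 1]).mean_derivative
    alpha3 = cubic_mean_trend(fit.beta_t[:, 3]).mean_derivative
    return alpha, alpha0, alpha1, alpha3


def _ols_slope(y: np.ndarray) -> float:
    t = np.arange(1, y.size + 1, dtype=float)
    return float(np.polyfit(t, y, 1)[0])


def ingredient_structure(
    fit: LWLRFit,
    cell: CellSeries,
    climate_derivative: str = "ols_slope",
) -> dict:
    """First-order decomposition of the climate-contribution trend.

    Neglecting the quadratic climate terms, the derivative of the
    climate contribution splits into four per-month terms::

        T(t) db1/dt  +  b1(t) dT/dt  +  P(t) db3/dt  +  b3(t) dP/dt

    Coefficient derivatives come from the cubic fits of ``b1(t)`` and
    ``b3(t)``; climate derivatives are the OLS linear slopes of the raw
    ``T`` and ``P`` series (``climate_derivative="ols_slope"``, default)
    or per-month central differences (``"finite_diff"``).

    Returns a dict with the per-month terms, their means, the
    temperature/precipitation mean shares, and a dominant-factor label:
    a factor is dominant when it carries at least 60% of the total
    absolute mean share, otherwise the label is ``"combination"``.
    """
    T, P = cell.temp, cell.precip
    m = cell.n_months
    t = np.arange(1, m + 1, dtype=float)
    cub1 = cubic_mean_trend(fit.beta_t[:, 1])
    cub3 = cubic_mean_trend(fit.beta_t[:, 3])
    c1, c3 = cub1.coefficients, cub3.coefficients
    db1 = 3 * c1[3] * t ** 2 + 2 * c1[2] * t + c1[1]
    db3 = 3 * c3[3] * t ** 2 + 2 * c3[2] * t + c3[1]
    if climate_derivative == "ols_slope":
        dT = np.full(m, _ols_slope(T))
        dP = np.full(m, _ols_slope(P))
    elif climate_derivative == "finite_diff":
        dT = np.gradient(T)
        dP = np.gradient(P)
    else:
        raise ValueError(f"unknown climate_derivative {climate_derivative!r}")
    terms = {
        "T_dbeta1": T * db1,
        "beta1_dT": fit.beta_t[:, 1] * dT,
        "P_dbeta3": P * db3,
        "beta3_dP": fit.beta_t[:, 3] * dP,
    }
    means = {k: float(v.mean()) for k, v in terms.items()}
    temp_share = abs(means["T_dbeta1"] + means["beta1_dT"])
    prec_share = abs(means["P_dbeta3"] + means["beta3_dP"])
    total = temp_share + prec_share
    if total == 0.0:
        label = "combination"
    elif temp_share / total >= 0.6:
        label = "temperature"
    elif prec_share / total >= 0.6:
        label = "precipitation"
    else:
        label = "combination"
    return {
        "terms": terms,
        "means": means,
        "approx_mean": float(sum(means.values())),
        "temperature_share": temp_share,
        "precipitation_share": prec_share,
        "dominant_factor": label,
    }


def relative_roles(
    alpha0: float, alpha: float, sig: float = ALPHA_SIG
) -> tuple[float, float, bool, str]:
    """Relative contribution ratios and the driver classification.

    ``Ra = alpha0 / (alpha0 + alpha)``, ``Rc = 1 - Ra``; the pair is
    undefined (flagged, not raised) when ``|alpha0 + alpha| < 1e-12``.
    ``Ra < 0`` means vegetation growth is degraded by anthropogenic
    activity while climate promotes it (or vice versa); the sign
    quadrant of ``(alpha0, alpha)`` gives a categorical driver class,
    with magnitudes below ``sig`` labelled insignificant.
    """
    if not (np.isfinite(alpha0) and np.isfinite(alpha)):
        raise ValueError("alpha0 and alpha must be finite")
    denom = alpha0 + alpha
    defined = abs(denom) >= 1e-12
    if defined:
        ra = alpha0 / denom
        rc = 1.0 - ra
    else:
        ra = rc = np.nan
    sig0 = abs(alpha0) >= sig
    sigc = abs(alpha) >= sig
    if not sig0 and not sigc:
        cls = "no significant trend"
    elif sig0 and not sigc:
        cls = "anthropogenic only " + ("promotes" if alpha0 > 0 else "degrades")
    elif sigc and not sig0:
        cls = "climate only " + ("promotes" if alpha > 0 else "degrades")
    elif alpha0 > 0 and alpha > 0:
        cls = "both promote"
    elif alpha0 > 0 > alpha:
        cls = "anthropogenic promotes, climate degrades"
    elif alpha > 0 > alpha0:
        cls = "climate promotes, anthropogenic degrades"
    else:
        cls = "both degrade"
    return float(ra), float(rc), defined, cls


def apnc_share(f_bar: float, g_bar: float, b0_bar: float) -> tuple[float, str, bool]:
    """Anthropogenic share of the total APNC, with its reporting bin.

    ``R_ac = b0_bar / (f_bar + g_bar + b0_bar)``; bins ``<=0.5``,
    ``(0.5, 0.75]``, ``(0.75, 1]`` and ``>1`` (the last arises when the
    climate APNC is negative).  Undefined (flagged) when the denominator
    is below tolerance.
    """
    denom = f_bar + g_bar + b0_bar
    if abs(denom) < 1e-12:
        return np.nan, "undefined", False
    r = b0_bar / denom
    if r <= 0.5:
        b = "<=0.5"
    elif r <= 0.75:
        b = "0.51-0.75"
    elif r <= 1.0:
        b = "0.76-1"
    else:
        b = ">1"
    return float(r), b, True


def monthly_slope_class(ndvi: np.ndarray, period: int = 12) -> tuple[float, str]:
    """OLS slope of the STL trend of NDVI and its greening class.

    Classes: ``degraded`` (slope < -2e-5 / month), ``non-significant``
    (within ±2e-5), ``promoted`` (> 2e-5) and ``strongly-promoted``
    (> 2e-4).
    """
    x = np.asarray(ndvi, dtype=float)
    if x.size < 24:
        raise ValueError("need at least 24 months")
    slope = _ols_slope(stl_trend(x, period=period))
    if slope > SLOPE_EXTREME:
        cls = "strongly-promoted"
    elif slope > SLOPE_THRESH:
        cls = "promoted"
    elif slope >= -SLOPE_THRESH:
        cls = "non-significant"
    else:
        cls = "degraded"
    return slope, cls


def attribute(fit: LWLRFit, cell: CellSeries) -> AttributionResult:
    """Run the full attribution chain for one fitted cell."""
    series = pnc_series(fit, cell)
    f_bar, g_bar, b0_bar, dominant = apnc(series)
    alpha, alpha0, alpha1, alpha3 = compute_alphas(series, fit)
    ra, rc, defined, cls = relative_roles(alpha0, alpha)
    r_ac, r_ac_bin, r_ac_def = apnc_share(f_bar, g_bar, b0_bar)
    ingredient = ingredient_structure(fit, cell)
    return AttributionResult(
        f_bar=f_bar, g_bar=g_bar, b0_bar=b0_bar,
        climate_bar=f_bar + g_bar, dominant_apnc=dominant,
        alpha=alpha, alpha0=alpha0, alpha1=alpha1, alpha3=alpha3,
        ra=ra, rc=rc, ratio_defined=defined, driver_class=cls,
        r_ac=r_ac, r_ac_bin=r_ac_bin, r_ac_defined=r_ac_def,
        ingredient=ingredient, dominant_factor=ingredient["dominant_factor"],
    )
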