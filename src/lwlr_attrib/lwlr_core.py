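"""Locally weighted linear regression (LWLR) with an asymmetric Gaussian kernel.

The model regresses a monthly NDVI series ``N(t)`` on quadratic climate
terms,

    N(t) = b0(t) + b1(t) T(t) + b2(t) T^2(t) + b3(t) P(t) + b4(t) P^2(t) + e(t),

where the coefficients are re-estimated at every focal month ``t`` by
weighted least squares.  The weights decay with temporal distance from
``t`` under a Gaussian kernel with separate left (past, ``h1``) and right
(future, ``h2``) bandwidths, so the effective sample window may be
asymmetric around the focal month.  The special case of constant
coefficients (uniform weights) is the ordinary global OLS fit, which is
also computed as a baseline for the explained-variance ratio ``Rlg``.

The time-varying intercept ``b0(t)`` is interpreted downstream as the
non-climatic (anthropogenic) component of NDVI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellSeries", "KernelSpec", "GlobalFit", "LWLRFit",
    "build_design", "kernel_weights", "weight_matrix",
    "fit_global", "fit_local", "fit_lwlr",
]

#: Minimum series length accepted for fitting (three seasonal cycles).
MIN_MONTHS = 36

#: Minimum bandwidth in months.  With five unknowns per local system the
#: kernel must keep a few effective observations in support even at the
#: series ends.
MIN_BANDWIDTH = 1.0


@dataclass(frozen=True)
class CellSeries:
    """Aligned monthly NDVI / temperature / precipitation series of one grid cell.

    Attributes
    ----------
    cell_id : str
        Identifier of the grid cell.
    lon, lat : float
        Cell centre coordinates in degrees.
    ndvi : ndarray
        NDVI series (unitless), length ``M``.
    temp : ndarray
        Temperature series (degrees Celsius), length ``M``.
    precip : ndarray
        Precipitation series (mm/month), length ``M``.
    start_month : int
        Calendar month (1-12) of the first observation; metadata only.
    """

    cell_id: str
    lon: float
    lat: float
    ndvi: np.ndarray
    temp: np.ndarray
    precip: np.ndarray
    start_month: int = 1

    def __post_init__(self):
        for name in ("ndvi", "temp", "precip"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if not (self.ndvi.shape == self.temp.shape == self.precip.shape):
            raise ValueError(
                f"series length mismatch in cell {self.cell_id!r}: "
                f"ndvi {self.ndvi.shape}, temp {self.temp.shape}, "
                f"precip {self.precip.shape}"
            )
        if self.ndvi.ndim != 1 or self.ndvi.size < MIN_MONTHS:
            raise ValueError(
                f"cell {self.cell_id!r}: need a 1-d series of at least "
                f"{MIN_MONTHS} months, got shape {self.ndvi.shape}"
            )
        for name in ("ndvi", "temp", "precip"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"cell {self.cell_id!r}: non-finite values in {name}")

    @property
    def n_months(self) -> int:
        return self.ndvi.size


@dataclass(frozen=True)
class KernelSpec:
    """Dual bandwidths of the asymmetric Gaussian kernel.

    ``h1`` scales the decay for months before the focal month, ``h2`` for
    the focal month and later.  Their ratio ``rh = h2 / h1`` encodes
    lead-lag structure between NDVI and climate: ``rh > 1`` is read as
    NDVI lagging behind the meteorological forcing, ``rh < 1`` as the
    converse.
    """

    h1: float
    h2: float

    def __post_init__(self):
        if not (np.isfinite(self.h1) and np.isfinite(self.h2)):
            raise ValueError("bandwidths must be finite")
        if self.h1 < MIN_BANDWIDTH or self.h2 < MIN_BANDWIDTH:
            raise ValueError(
                f"bandwidths must be >= {MIN_BANDWIDTH} month, got "
                f"h1={self.h1}, h2={self.h2}"
            )

    @property
    def rh(self) -> float:
        """Bandwidth ratio h2/h1."""
        return self.h2 / self.h1


@dataclass
class GlobalFit:
    """Constant-coefficient OLS fit of NDVI on the quadratic climate design."""

    beta: np.ndarray            # (5,) coefficients [b0, b1, b2, b3, b4]
    fitted: np.ndarray          # (M,)
    residuals: np.ndarray       # (M,)
    rg2: float                  # explained-variance determinable coefficient
    rank_deficient: bool = False
    degenerate_variance: bool = False


@dataclass
class LWLRFit:
    """Time-varying-coefficient fit with per-month coefficient trajectories.

    ``beta_t[t - 1]`` holds ``[b0(t), b1(t), b2(t), b3(t), b4(t)]`` for
    month ``t``.  ``rl2`` is the explained-variance statistic of the local
    model and ``rlg = rl2 / rg2`` compares it with the global OLS
    baseline; ``rlg > 1`` means the local model explains more NDVI
    variance.  ``boundary_flag[t - 1]`` marks months within
    ``max(h1, h2)`` of either series end, where the asymmetric kernel is
    truncated and trajectories may show end-point artefacts.
    """

    beta_t: np.ndarray          # (M, 5)
    fitted: np.ndarray          # (M,)
    residuals: np.ndarray       # (M,)
    rl2: float
    rg2: float
    rlg: float
    kernel: KernelSpec
    boundary_flag: np.ndarray   # (M,) bool
    singular_flag: np.ndarray = field(default=None)  # (M,) bool, pseudo-inverse fallback

    @property
    def n_months(self) -> int:
        return self.beta_t.shape[0]


def build_design(temp: np.ndarray, precip: np.ndarray) -> np.ndarray:
    """Quadratic climate design matrix ``[1, T, T^2, P, P^2]``.

    Parameters
    ----------
    temp, precip : array-like, shape (M,)
        Temperature and precipitation series of equal length.

    Returns
    -------
    ndarray, shape (M, 5)
    """
    t = np.asarray(temp, dtype=float)
    p = np.asarray(precip, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError(f"temp and precip must be 1-d and equal length, got {t.shape} vs {p.shape}")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
        raise ValueError("non-finite values in climate series")
    return np.column_stack([np.ones_like(t), t, t * t, p, p * p])


def kernel_weights(t: int, n_months: int, spec: KernelSpec) -> np.ndarray:
    """Asymmetric Gaussian weights of every month ``j`` relative to focal ``t``.

    ``W(j, t) = exp(-((j - t) / h1)^2 / 2)`` for ``j < t`` and the same
    with ``h2`` for ``j >= t``; months are 1-based.  ``W(t, t) = 1``.
    """
    if not 1 <= t <= n_months:
        raise ValueError(f"focal month t={t} outside 1..{n_months}")
    j = np.arange(1, n_months + 1, dtype=float)
    d = j - t
    h = np.where(d < 0, spec.h1, spec.h2)
    return np.exp(-0.5 * (d / h) ** 2)


def weight_matrix(n_months: int, spec: KernelSpec) -> np.ndarray:
    """All kernel weights as a matrix ``W[t - 1, j - 1] = W(j, t)``."""
    j = np.arange(1, n_months + 1, dtype=float)
    d = j[None, :] - j[:, None]          # d[t-1, j-1] = j - t
    h = np.where(d < 0, spec.h1, spec.h2)
    return np.exp(-0.5 * (d / h) ** 2)


def _explained_variance(fitted: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Ratio sum[(yhat - ybar)^2] / sum[(y - ybar)^2] with a zero-variance flag."""
    sst = float(np.sum((y - y.mean()) ** 2))
    # relative zero test: constant series leave only rounding dust in sst
    if sst <= np.finfo(float).eps * y.size * max(float(np.sum(y * y)), 1.0):
        return np.nan, True
    return float(np.sum((fitted - y.mean()) ** 2) / sst), False


def fit_global(cell: CellSeries) -> GlobalFit:
    """Constant-coefficient OLS baseline fit.

    Solves ``min_b sum_t (N(t) - X(t) b)^2`` for the quadratic climate
    design and reports the explained-variance statistic.  A
    rank-deficient design is solved by pseudo-inverse and flagged with a
    warning.
    """
    X = build_design(cell.temp, cell.precip)
    y = cell.ndvi
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rank_deficient = rank < X.shape[1]
    if rank_deficient:
        warnings.warn(
            f"cell {cell.cell_id!r}: rank-deficient design (rank {rank} < 5); "
            "coefficients are a pseudo-inverse solution",
            stacklevel=2,
        )
    fitted = X @ beta
    rg2, degenerate = _explained_variance(fitted, y)
    if degenerate:
        warnings.warn(
            f"cell {cell.cell_id!r}: NDVI has zero variance, Rg2 undefined",
            stacklevel=2,
        )
    return GlobalFit(beta=beta, fitted=fitted, residuals=y - fitted,
                     rg2=rg2, rank_deficient=rank_deficient,
                     degenerate_variance=degenerate)


def _solve_weighted(X: np.ndarray, y: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batch-solve ``(X' diag(W[t]) X) b(t) = X' diag(W[t]) y`` for all focal t.

    ``W`` has one row of weights per focal month.  Returns the ``(M, k)``
    coefficient matrix and a boolean flag per focal month marking systems
    that needed a pseudo-inverse (numerically singular moment matrix).
    """
    A = np.einsum("tj,ji,jk->tik", W, X, X, optimize=True)
    b = np.einsum("tj,ji,j->ti", W, X, y, optimize=True)
    n_t, k = b.shape
    beta = np.empty((n_t, k))
    singular = np.zeros(n_t, dtype=bool)
    # condition-based routing: solve the well-posed systems in one batch
    with np.errstate(all="ignore"):
        cond = np.linalg.cond(A)
    bad = (~np.isfinite(cond)) | (cond > 1 / np.finfo(float).eps)
    good = ~bad
    if np.any(good):
        beta[good] = np.linalg.solve(A[good], b[good][..., None])[..., 0]
    for i in np.nonzero(bad)[0]:
        beta[i] = np.linalg.pinv(A[i]) @ b[i]
        singular[i] = True
    return beta, singular


def fit_local(t: int, cell: CellSeries, spec: KernelSpec) -> np.ndarray:
    """Coefficient vector ``[b0(t), .., b4(t)]`` at one focal month.

    Minimises the kernel-weighted sum of squares
    ``sum_j W(j, t) [N(j) - b0 - sum_i bi x_i(j)]^2`` via the weighted
    normal equations.  Singular moment matrices fall back to the
    pseudo-inverse (flag raised as a warning).
    """
    X = build_design(cell.temp, cell.precip)
    w = kernel_weights(t, cell.n_months, spec)
    beta, singular = _solve_weighted(X, cell.ndvi, w[None, :])
    if singular[0]:
        warnings.warn(
            f"cell {cell.cell_id!r}, t={t}: singular weighted moment matrix, "
            "pseudo-inverse fallback",
            stacklevel=2,
        )
    return beta[0]


def fit_lwlr(cell: CellSeries, spec: KernelSpec, global_fit: GlobalFit | None = None) -> LWLRFit:
    """Full time-varying-coefficient fit over all months of a cell.

    Parameters
    ----------
    cell : CellSeries
    spec : KernelSpec
        Kernel bandwidths (typically from cross-validation).
    global_fit : GlobalFit, optional
        Precomputed OLS baseline; fitted here when omitted.

    Returns
    -------
    LWLRFit
        Coefficient trajectories, fitted series, residuals, the
        explained-variance statistics and per-month boundary and
        singularity flags.

    Notes
    -----
    The explained-variance form ``sum[(fitted - mean(N))^2] /
    sum[(N - mean(N))^2]`` is used for both the local and the global
    statistic.  For the local model fitted values and residuals do not
    partition the total sum of squares, so ``rl2`` may exceed 1 for
    aggressive (small) bandwidths.
    """
    if global_fit is None:
        global_fit = fit_global(cell)
    X = build_design(cell.temp, cell.precip)
    W = weight_matrix(cell.n_months, spec)
    beta_t, singular = _solve_weighted(X, cell.ndvi, W)
    fitted = np.einsum("ti,ti->t", X, beta_t)
    residuals = cell.ndvi - fitted
    rl2, _ = _explained_variance(fitted, cell.ndvi)
    rlg = rl2 / global_fit.rg2 if np.isfinite(global_fit.rg2) else np.nan
    m = cell.n_months
    reach = int(np.ceil(max(spec.h1, spec.h2)))
    t_idx = np.arange(1, m + 1)
    boundary = (t_idx <= reach) | (t_idx > m - reach)
    return LWLRFit(beta_t=beta_t, fitted=fitted, residuals=residuals,
                   rl2=rl2, rg2=global_fit.rg2, rlg=rlg, kernel=spec,
                   boundary_flag=boundary, singular_flag=singular)
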