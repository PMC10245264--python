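"""Dual-bandwidth selection by leave-one-out cross-validation.

For each candidate ``(h1, h2)`` pair the predicted value at month ``t``
is computed with month ``t`` removed from the calibration set (its
kernel weight set to zero), and the candidate minimising the summed
squared prediction error ``CV(h) = sum_t (N(t) - Nhat_{-t}(t))^2`` is
selected.  The search is an exhaustive scan of a Cartesian candidate
grid; with monthly series of a few hundred points this is cheap because
all local solves are batched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lwlr_core import CellSeries, KernelSpec, build_design, weight_matrix, _solve_weighted

__all__ = ["DEFAULT_GRID", "CVResult", "loo_predict", "cv_score", "select_bandwidths"]

#: Default candidate bandwidths (months) for each side of the kernel;
#: the candidate set is their full Cartesian product.
DEFAULT_GRID: tuple[float, ...] = (1, 2, 3, 4, 6, 9, 12, 18, 24, 36, 48)


@dataclass
class CVResult:
    """Outcome of an exhaustive bandwidth scan."""

    grid: list[tuple[float, float]]
    scores: np.ndarray          # CV sum of squared LOO errors per candidate
    rmse: np.ndarray            # root mean squared LOO error per candidate
    best: KernelSpec
    score_best: float


def _loo_predictions(cell: CellSeries, spec: KernelSpec) -> np.ndarray:
    """Leave-one-out predicted NDVI at every month under one kernel spec."""
    X = build_design(cell.temp, cell.precip)
    W = weight_matrix(cell.n_months, spec)
    np.fill_diagonal(W, 0.0)            # drop the focal month from its own fit
    beta_t, _ = _solve_weighted(X, cell.ndvi, W)
    return np.einsum("ti,ti->t", X, beta_t)


def loo_predict(t: int, cell: CellSeries, spec: KernelSpec) -> float:
    """Predicted NDVI at month ``t`` with month ``t`` left out of the fit."""
    if not 1 <= t <= cell.n_months:
        raise ValueError(f"focal month t={t} outside 1..{cell.n_months}")
    return float(_loo_predictions(cell, spec)[t - 1])


def cv_score(cell: CellSeries, spec: KernelSpec) -> float:
    """Sum over months of squared leave-one-out prediction errors."""
    pred = _loo_predictions(cell, spec)
    err2 = (cell.ndvi - pred) ** 2
    if not np.all(np.isfinite(err2)):
        t_bad = int(np.nonzero(~np.isfinite(err2))[0][0]) + 1
        raise FloatingPointError(f"non-finite leave-one-out prediction at t={t_bad}")
    return float(err2.sum())


def select_bandwidths(
    cell: CellSeries,
    grid_h1: tuple[float, ...] = DEFAULT_GRID,
    grid_h2: tuple[float, ...] | None = None,
) -> CVResult:
    """Exhaustive leave-one-out scan over the (h1, h2) candidate grid.

    Ties on the CV score are broken in favour of (1) the smaller
    ``h1 + h2`` (prefer the less flexible description only when it costs
    nothing -- smaller total bandwidth means fewer effective parameters
    on neither side), then (2) the ratio ``h2/h1`` closest to 1, then
    (3) lexicographic order, so selection is deterministic.
    """
    if grid_h2 is None:
        grid_h2 = grid_h1
    candidates = [(float(a), float(b)) for a in grid_h1 for b in grid_h2]
    if not candidates:
        raise ValueError("empty candidate grid")
    scores = np.empty(len(candidates))
    for i, (a, b) in enumerate(candidates):
        try:
            scores[i] = cv_score(cell, KernelSpec(a, b))
        except FloatingPointError:
            scores[i] = np.inf
    if not np.any(np.isfinite(scores)):
        raise FloatingPointError("all candidate bandwidths produced non-finite CV scores")

    def sort_key(i: int):
        a, b = candidates[i]
        return (scores[i], a + b, abs(b / a - 1.0), a, b)

    best_i = min(range(len(candidates)), key=sort_key)
    h1, h2 = candidates[best_i]
    rmse = np.sqrt(scores / cell.n_months)
    return CVResult(grid=candidates, scores=scores, rmse=rmse,
                    best=KernelSpec(h1, h2), score_best=float(scores[best_i]))
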