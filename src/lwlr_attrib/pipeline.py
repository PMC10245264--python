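"""Per-cell orchestration and batch processing over grids.

Workflow per cell: mask (no-vegetation screen) -> collinearity check ->
bandwidth selection by leave-one-out CV -> locally weighted fit ->
Durbin-Watson -> Cochrane-Orcutt correction when autocorrelation is
detected -> residual-normality screen -> attribution.  Cells fail in
isolation; a batch always produces a record per cell plus summary
statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lwlr_core import CellSeries, KernelSpec, fit_global, fit_lwlr, build_design, weight_matrix
from .bandwidth_cv import DEFAULT_GRID, select_bandwidths
from .diagnostics import (
    DW_BAND, VIF_WARN, DiagnosticsReport,
    weighted_vif, durbin_watson, cochrane_orcutt, delta_p, normality_test,
)
from .attribution import AttributionResult, attribute, monthly_slope_class

__all__ = [
    "RunConfig", "CellOutcome", "mask_cells", "run_cell", "run_grid",
    "read_long_csv", "write_long_csv", "write_outputs", "outcomes_to_frame",
]

log = logging.getLogger("lwlr_attrib")

#: Reporting bins for the local/global explained-variance ratio.
RLG_BINS = ((1.00, 1.10), (1.11, 1.20), (1.21, 1.30), (1.31, 1.40), (1.41, 1.50))


@dataclass
class RunConfig:
    """All pipeline settings; round-trips losslessly through YAML."""

    mask_threshold: float = 0.15
    cv_grid_h1: tuple[float, ...] = DEFAULT_GRID
    cv_grid_h2: tuple[float, ...] = DEFAULT_GRID
    tau: float = 0.04               # Monte-Carlo calibrated default
    dw_band: tuple[float, float] = DW_BAND
    co_max_iter: int = 20
    co_tol: float = 1e-3
    alpha_sig: float = 5e-6
    slope_threshold: float = 2e-5
    slope_extreme: float = 2e-4
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0.0 < self.mask_threshold < 1.0:
            raise ValueError("mask_threshold must lie in (0, 1)")
        for name in ("tau", "alpha_sig", "slope_threshold", "slope_extreme"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.cv_grid_h1 = tuple(float(h) for h in self.cv_grid_h1)
        self.cv_grid_h2 = tuple(float(h) for h in self.cv_grid_h2)
        self.dw_band = tuple(float(v) for v in self.dw_band)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["cv_grid_h1"] = list(d["cv_grid_h1"])
        d["cv_grid_h2"] = list(d["cv_grid_h2"])
        d["dw_band"] = list(d["dw_band"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


@dataclass
class CellOutcome:
    """Result record for one cell: masked, fitted, or failed."""

    cell_id: str
    lon: float
    lat: float
    status: str                                 # "masked" | "fitted" | "failed"
    reason: str = ""
    kernel: KernelSpec | None = None
    rg2: float = np.nan
    rl2: float = np.nan
    rlg: float = np.nan
    diagnostics: DiagnosticsReport | None = None
    attribution: AttributionResult | None = None
    slope: float = np.nan
    slope_class: str = ""
    boundary_fraction: float = np.nan
    timings: dict = field(default_factory=dict)


def mask_cells(
    cells: list[CellSeries], threshold: float = 0.15
) -> tuple[list[CellSeries], list[CellSeries]]:
    """Partition cells into (kept, excluded) by the no-vegetation rule.

    A cell is excluded when its mean NDVI over the record is less than
    or equal to ``threshold`` (boundary inclusive).
    """
    kept, excluded = [], []
    for c in cells:
        (excluded if float(np.mean(c.ndvi)) <= threshold else kept).append(c)
    return kept, excluded


def run_cell(cell: CellSeries, config: RunConfig | None = None) -> CellOutcome:
    """Run the full diagnose/select/fit/attribute chain on one cell.

    Any stage failure is caught and recorded (status ``"failed"`` with
    the stage name); the function never raises for data-dependent
    problems, so batch runs are fault-isolated.
    """
    config = config or RunConfig()
    out = CellOutcome(cell_id=cell.cell_id, lon=cell.lon, lat=cell.lat, status="failed")
    stage = "start"
    t_all = time.perf_counter()
    try:
        stage = "bandwidth-cv"
        t0 = time.perf_counter()
        cv = select_bandwidths(cell, config.cv_grid_h1, config.cv_grid_h2)
        spec = cv.best
        out.kernel = spec
        out.timings[stage] = time.perf_counter() - t0

        stage = "vif"
        t0 = time.perf_counter()
        X = build_design(cell.temp, cell.precip)
        W = weight_matrix(cell.n_months, spec)
        _, vif_max = weighted_vif(X, W)
        out.timings[stage] = time.perf_counter() - t0

        stage = "fit"
        t0 = time.perf_counter()
        gfit = fit_global(cell)
        fit = fit_lwlr(cell, spec, gfit)
        out.rg2, out.rl2, out.rlg = fit.rg2, fit.rl2, fit.rlg
        out.boundary_fraction = float(np.mean(fit.boundary_flag))
        out.timings[stage] = time.perf_counter() - t0

        stage = "durbin-watson"
        degenerate = bool(np.allclose(fit.residuals, 0.0, atol=1e-12))
        if degenerate:
            dw, in_band = np.nan, True
        else:
            dw = durbin_watson(fit.residuals)
            in_band = config.dw_band[0] <= dw <= config.dw_band[1]

        stage = "cochrane-orcutt"
        rho, co_iter, co_conv = 0.0, 0, True
        resid_for_normality = fit.residuals
        attribution_fit = fit
        if not degenerate and not in_band:
            co_fit, rho, co_iter, co_conv = cochrane_orcutt(
                cell, spec, max_iter=config.co_max_iter, tol=config.co_tol)
            resid_for_normality = co_fit.residuals
            attribution_fit = co_fit
            dw = durbin_watson(co_fit.residuals)

        stage = "normality"
        if degenerate or np.std(resid_for_normality) == 0.0:
            dp, normal = np.nan, False
            degenerate = True
        else:
            dp = delta_p(resid_for_normality)
            normal = normality_test(dp, config.tau)

        out.diagnostics = DiagnosticsReport(
            vif_max=vif_max, vif_flag=not vif_max < VIF_WARN,
            dw=dw, dw_in_band=bool(degenerate or config.dw_band[0] <= dw <= config.dw_band[1]),
            rho=rho, co_iterations=co_iter, co_converged=co_conv,
            delta_p=dp, tau=config.tau, normal_pass=bool(normal),
            degenerate_residuals=degenerate,
        )

        stage = "attribution"
        if attribution_fit.n_months == cell.n_months:
            attr_cell = cell
        else:
            # Cochrane-Orcutt path: trajectories start at month 2
            attr_cell = CellSeries(cell_id=cell.cell_id, lon=cell.lon, lat=cell.lat,
                                   ndvi=cell.ndvi[1:], temp=cell.temp[1:],
                                   precip=cell.precip[1:])
        out.attribution = attribute(attribution_fit, attr_cell)

        stage = "slope-class"
        out.slope, out.slope_class = monthly_slope_class(cell.ndvi)

        out.status = "fitted"
        log.info("cell %s fitted: h=(%g,%g) rlg=%.3f dw=%.2f dp=%s in %.2fs",
                 cell.cell_id, spec.h1, spec.h2, out.rlg, dw,
                 f"{dp:.3f}" if np.isfinite(dp) else "n/a",
                 time.perf_counter() - t_all)
    except Exception as exc:  # noqa: BLE001 - fault isolation is the contract
        out.status = "failed"
        out.reason = f"{stage}: {exc}"
        log.warning("cell %s failed at %s: %s", cell.cell_id, stage, exc)
    out.timings["total"] = time.perf_counter() - t_all
    return out


def _rlg_bin(rlg: float) -> str:
    if not np.isfinite(rlg):
        return "undefined"
    for lo, hi in RLG_BINS:
        if lo <= rlg <= hi:
            return f"{lo:.2f}-{hi:.2f}"
    return ">1.50" if rlg > 1.50 else "<1.00"


def run_grid(
    cells: list[CellSeries], config: RunConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Process a grid of cells and summarise the batch.

    Returns the per-cell record table and a summary dict with the
    masked fraction, explained-variance-ratio bin counts, normality
    pass fractions, and driver-ratio bin fractions.
    """
    config = config or RunConfig()
    ids = [c.cell_id for c in cells]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell_id in input grid")
    kept, excluded = mask_cells(cells, config.mask_threshold)
    outcomes = [CellOutcome(cell_id=c.cell_id, lon=c.lon, lat=c.lat,
                            status="masked", reason="mean NDVI <= threshold")
                for c in excluded]
    outcomes += [run_cell(c, config) for c in kept]
    table = outcomes_to_frame(outcomes)

    fitted = table[table.status == "fitted"]
    n = len(cells)
    summary = {
        "n_cells": n,
        "n_masked": int((table.status == "masked").sum()),
        "n_fitted": int(len(fitted)),
        "n_failed": int((table.status == "failed").sum()),
        "masked_fraction": float((table.status == "masked").sum() / n),
        "rlg_bins": fitted.groupby(fitted.rlg.map(_rlg_bin)).size().to_dict() if len(fitted) else {},
        "normal_pass_fraction": float(fitted.normal_pass.mean()) if len(fitted) else np.nan,
        "dw_in_band_fraction": float(fitted.dw_in_band.mean()) if len(fitted) else np.nan,
        "mean_ra": float(fitted.ra.mean()) if len(fitted) else np.nan,
        "mean_rc": float(fitted.rc.mean()) if len(fitted) else np.nan,
        "ra_positive_fraction": float((fitted.ra > 0).mean()) if len(fitted) else np.nan,
        "r_ac_bins": fitted.groupby("r_ac_bin").size().to_dict() if len(fitted) else {},
        "alpha_positive_fraction": float((fitted.alpha > config.alpha_sig).mean()) if len(fitted) else np.nan,
        "alpha0_positive_fraction": float((fitted.alpha0 > config.alpha_sig).mean()) if len(fitted) else np.nan,
        "slope_classes": fitted.groupby("slope_class").size().to_dict() if len(fitted) else {},
    }
    return table, summary


def outcomes_to_frame(outcomes: list[CellOutcome]) -> pd.DataFrame:
    """Flatten CellOutcome records into the per-cell results table."""
    rows = []
    for o in outcomes:
        d = o.diagnostics
        a = o.attribution
        rows.append({
            "cell_id": o.cell_id, "lon": o.lon, "lat": o.lat,
            "status": o.status, "reason": o.reason,
            "h1": o.kernel.h1 if o.kernel else np.nan,
            "h2": o.kernel.h2 if o.kernel else np.nan,
            "rh": o.kernel.rh if o.kernel else np.nan,
            "rg2": o.rg2, "rl2": o.rl2, "rlg": o.rlg,
            "vif_max": d.vif_max if d else np.nan,
            "dw": d.dw if d else np.nan,
            "dw_in_band": d.dw_in_band if d else False,
            "rho": d.rho if d else np.nan,
            "co_iterations": d.co_iterations if d else 0,
            "delta_p": d.delta_p if d else np.nan,
            "normal_pass": d.normal_pass if d else False,
            "f_bar": a.f_bar if a else np.nan,
            "g_bar": a.g_bar if a else np.nan,
            "b0_bar": a.b0_bar if a else np.nan,
            "r_ac": a.r_ac if a else np.nan,
            "r_ac_bin": a.r_ac_bin if a else "",
            "alpha": a.alpha if a else np.nan,
            "alpha0": a.alpha0 if a else np.nan,
            "alpha1": a.alpha1 if a else np.nan,
            "alpha3": a.alpha3 if a else np.nan,
            "ra": a.ra if a else np.nan,
            "rc": a.rc if a else np.nan,
            "driver_class": a.driver_class if a else "",
            "dominant_factor": a.dominant_factor if a else "",
            "slope": o.slope, "slope_class": o.slope_class,
            "boundary_fraction": o.boundary_fraction,
        })
    return pd.DataFrame(rows)


def read_long_csv(path: str | Path) -> tuple[list[CellSeries], list[dict]]:
    """Read a long-format grid CSV into cells, rejecting incomplete ones.

    Expected columns: ``cell_id, lon, lat, date (YYYY-MM), ndvi, temp,
    precip``.  A cell must cover every month between its first and last
    date exactly once; offending cells are rejected (returned in the
    second list with a reason) while the rest load normally.
    """
    df = pd.read_csv(path, dtype={"cell_id": str})
    required = {"cell_id", "lon", "lat", "date", "ndvi", "temp", "precip"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    try:
        df["date"] = pd.PeriodIndex(df["date"], freq="M")
    except Exception as exc:
        raise ValueError(f"malformed date column in {path}: {exc}") from None
    cells, rejected = [], []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("date")
        dates = grp["date"]
        if dates.duplicated().any():
            rejected.append({"cell_id": cid, "reason": "duplicate months"})
            continue
        expected = pd.period_range(dates.iloc[0], dates.iloc[-1], freq="M")
        if len(expected) != len(dates) or not (dates.to_numpy() == expected.to_numpy()).all():
            rejected.append({"cell_id": cid, "reason": "missing months"})
            continue
        try:
            cells.append(CellSeries(
                cell_id=str(cid),
                lon=float(grp["lon"].iloc[0]), lat=float(grp["lat"].iloc[0]),
                ndvi=grp["ndvi"].to_numpy(float),
                temp=grp["temp"].to_numpy(float),
                precip=grp["precip"].to_numpy(float),
                start_month=int(dates.iloc[0].month),
            ))
        except ValueError as exc:
            rejected.append({"cell_id": cid, "reason": str(exc)})
    return cells, rejected


def write_long_csv(cells: list[CellSeries], path: str | Path,
                   start: str = "2000-01") -> None:
    """Write cells to the long-format CSV consumed by :func:`read_long_csv`."""
    frames = []
    for c in cells:
        dates = pd.period_range(start, periods=c.n_months, freq="M")
        frames.append(pd.DataFrame({
            "cell_id": c.cell_id, "lon": c.lon, "lat": c.lat,
            "date": dates.astype(str),
            "ndvi": c.ndvi, "temp": c.temp, "precip": c.precip,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def write_outputs(
    table: pd.DataFrame,
    summary: dict,
    out_dir: str | Path,
    netcdf: bool = False,
) -> dict[str, Path]:
    """Write the per-cell table (CSV), summary (JSON) and optional NetCDF."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    csv_path = out_dir / "cells.csv"
    table.to_csv(csv_path, index=False, float_format="%.10g")
    paths["cells"] = csv_path
    json_path = out_dir / "summary.json"
    json_path.write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True))
    paths["summary"] = json_path
    if netcdf:
        paths["netcdf"] = _write_netcdf(table, out_dir / "cells.nc")
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _write_netcdf(table: pd.DataFrame, path: Path) -> Path:
    """Scatter per-cell scalars onto the lat/lon grid (CF-style dims)."""
    import xarray as xr

    lats = np.sort(table.lat.unique())
    lons = np.sort(table.lon.unique())
    fields = ["rg2", "rl2", "rlg", "f_bar", "g_bar", "b0_bar",
              "alpha", "alpha0", "ra", "rc", "r_ac", "slope"]
    data = {}
    for f in fields:
        grid = np.full((lats.size, lons.size), np.nan)
        for _, row in table.iterrows():
            i = np.searchsorted(lats, row.lat)
            j = np.searchsorted(lons, row.lon)
            grid[i, j] = row[f]
        data[f] = (("lat", "lon"), grid)
    ds = xr.Dataset(data, coords={"lat": lats, "lon": lons})
    ds.lat.attrs.update(units="degrees_north", standard_name="latitude")
    ds.lon.attrs.update(units="degrees_east", standard_name="longitude")
    ds.to_netcdf(path, engine="scipy")
    return path
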