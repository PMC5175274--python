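"""Statistical downscaling of coarse model SST onto the fine grid.

The adjustment chain, applied per model and scenario:

1. ``fill_zonal`` — land-masked coarse cells are filled by 1-D
   interpolation along each latitude row (linear between valid
   neighbours, nearest value at row ends);
2. ``regrid_bilinear`` — the coarse fields are interpolated bilinearly
   to the fine-grid cell centers;
3. ``substitute_annual_cycle`` — the model's own annual cycle (its
   per-calendar-month means over a reference window) is replaced by the
   observed climatological cycle, preserving model anomalies exactly;
4. ``recenter_baseline`` — a per-pixel constant is removed so the
   baseline-window (2006-2011) mean equals the observed climatology's
   overall mean at that pixel.

The result is a fine-grid series with a locally relevant present-day
mean and annual cycle, carrying only the model's projected anomalies on
top.  Trends and variability are untouched: steps 3-4 are additive
constants per pixel (and calendar month).
"""

from __future__ import annotations

import logging

import numpy as np
import xarray as xr

from .climatology import compute_mmm
from .params import AnalysisParams, default_params

__all__ = [
    "fill_zonal",
    "regrid_bilinear",
    "substitute_annual_cycle",
    "recenter_baseline",
    "downscale_model",
]

log = logging.getLogger(__name__)


def _is_global_lon(lon: np.ndarray) -> bool:
    if lon.size < 2:
        return False
    step = float(lon[1] - lon[0])
    return abs((lon[-1] - lon[0]) + step - 360.0) < 1e-6


def _zonal_fill_rows(values: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Fill NaNs along the last axis: linear between valid neighbours,
    nearest valid value beyond the ends (``np.interp`` semantics).
    All-NaN rows pass through unchanged."""
    out = values.copy()
    flat = out.reshape(-1, out.shape[-1])
    finite = np.isfinite(flat)
    for r in range(flat.shape[0]):
        m = finite[r]
        if m.all() or not m.any():
            continue
        flat[r] = np.interp(lon, lon[m], flat[r, m])
    return out


def fill_zonal(field: xr.DataArray, periodic: bool | None = None) -> xr.DataArray:
    """Fill missing values along each latitude row by zonal interpolation.

    Interior gaps are filled linearly in longitude between the nearest
    valid neighbours; gaps at the row ends take the nearest valid value.
    Rows with no valid values at all pass through missing.  When
    ``periodic`` (default: auto-detected from the longitude span) the
    row wraps across the antimeridian, so end gaps interpolate across
    the seam instead of taking the nearest value.
    """
    lon = np.asarray(field["lon"], dtype=float)
    if periodic is None:
        periodic = _is_global_lon(lon)
    da = field.transpose(..., "lon")
    arr = np.asarray(da.values, dtype=float)
    if periodic:
        n = lon.size
        lon_ext = np.concatenate([lon - 360.0, lon, lon + 360.0])
        arr_ext = np.concatenate([arr, arr, arr], axis=-1)
        filled = _zonal_fill_rows(arr_ext, lon_ext)[..., n : 2 * n]
    else:
        filled = _zonal_fill_rows(arr, lon)
    return da.copy(data=filled).transpose(*field.dims)


def regrid_bilinear(field: xr.DataArray, fine_lat: np.ndarray, fine_lon: np.ndarray) -> xr.DataArray:
    """Bilinear interpolation from coarse cell centers to fine cell centers.

    Fine points outside the hull of coarse centers are clamped to the
    edge coordinate first, i.e. nearest-edge extrapolation (logged).
    """
    out = field
    for dim, targets in (("lat", fine_lat), ("lon", fine_lon)):
        targets = np.asarray(targets, dtype=float)
        src = np.asarray(out[dim], dtype=float)
        clamped = np.clip(targets, src.min(), src.max())
        n_out = int((clamped != targets).sum())
        if n_out:
            log.info("regrid_bilinear: %d fine %s coordinates outside the coarse "
                     "hull use nearest-edge extrapolation", n_out, dim)
        if src.size == 1:
            # degenerate axis: broadcast the single coarse row/column
            idx = xr.DataArray(np.zeros(targets.size, dtype=int), dims=dim)
            out = out.isel({dim: idx})
        else:
            out = out.interp({dim: xr.DataArray(clamped, dims=dim)},
                             method="linear", assume_sorted=True)
        out = out.assign_coords({dim: targets})
    return out


def model_annual_cycle(series: xr.DataArray, window: tuple[int, int]) -> xr.DataArray:
    """Per-calendar-month means of a series over an inclusive year window."""
    y0, y1 = window
    sel = series.sel(time=(series["time.year"] >= y0) & (series["time.year"] <= y1))
    if sel.sizes["time"] == 0:
        raise ValueError(f"series does not cover the cycle window {y0}-{y1}")
    return sel.groupby("time.month").mean("time")


def substitute_annual_cycle(
    series: xr.DataArray,
    model_cycle: xr.DataArray,
    obs_cycle: xr.DataArray,
) -> xr.DataArray:
    """Swap the model's annual cycle for the observed one.

    ``value(pixel, t) - model_cycle[month(t)] + obs_cycle[month(t)]``:
    anomalies relative to the model's own cycle are preserved exactly.
    ``model_cycle`` and ``obs_cycle`` are 12-month fields with a
    ``month`` dimension on the series' grid.
    """
    anomaly = series.groupby("time.month") - model_cycle
    out = anomaly.groupby("time.month") + obs_cycle
    if "month" in out.coords:
        out = out.drop_vars("month")
    return out.rename(series.name).assign_attrs(series.attrs)


def recenter_baseline(
    series: xr.DataArray,
    clim: xr.Dataset,
    params: AnalysisParams | None = None,
) -> xr.DataArray:
    """Pin the baseline-window mean to the climatology's overall mean.

    Subtracts one constant per pixel; trends and variability are
    unchanged.
    """
    if params is None:
        params = default_params()
    b0, b1 = params.baseline_window
    base = series.sel(time=(series["time.year"] >= b0) & (series["time.year"] <= b1))
    if base.sizes["time"] == 0:
        raise ValueError(f"series does not cover the baseline window {b0}-{b1}")
    offset = base.mean("time") - clim["overall_mean"]
    return (series - offset).rename(series.name).assign_attrs(series.attrs)


def downscale_model(
    model: xr.DataArray,
    clim: xr.Dataset,
    params: AnalysisParams | None = None,
    cycle_window: tuple[int, int] | None = None,
    periodic: bool | None = None,
) -> xr.DataArray:
    """Full adjustment chain for one coarse model series.

    ``cycle_window`` sets the years used to estimate the model's own
    annual cycle; by default the baseline window, which makes the
    baseline constraints hold exactly by construction.
    """
    if params is None:
        params = default_params()
    if cycle_window is None:
        cycle_window = params.baseline_window
    p0, p1 = params.projection_window
    years = model["time.year"]
    if int(years.min()) > p0 or int(years.max()) < p1:
        raise ValueError(f"model series does not cover {p0}-{p1}")

    filled = fill_zonal(model, periodic=periodic)
    fine = regrid_bilinear(filled, np.asarray(clim["lat"]), np.asarray(clim["lon"]))
    cycle = model_annual_cycle(fine, cycle_window)
    swapped = substitute_annual_cycle(fine, cycle, clim["monthly_mean"])
    out = recenter_baseline(swapped, clim, params)
    # pixels flagged missing in the climatology stay missing downstream
    out = out.where(clim["overall_mean"].notnull())
    return out.rename("sst").assign_attrs(model.attrs)
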