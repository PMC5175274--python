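"""Observed monthly climatology and the maximum monthly mean (MMM).

The MMM — the warmest of the twelve long-term monthly mean temperatures
at a pixel — is the bleaching threshold baseline: heat stress accumulates
only while SST sits above it.  The climatology's overall mean (mean of
the twelve monthly means) is the anchor the downscaled model baseline is
pinned to.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .params import AnalysisParams, default_params

__all__ = ["compute_monthly_climatology", "compute_mmm"]


def compute_monthly_climatology(
    obs: xr.DataArray,
    window: tuple[int, int] | None = None,
    params: AnalysisParams | None = None,
) -> xr.Dataset:
    """Per-calendar-month mean SST over a year window, plus MMM.

    Parameters
    ----------
    obs
        Monthly SST series ``(time, lat, lon)``; NaN marks missing.
    window
        Inclusive ``(first, last)`` years; defaults to the analysis
        climatology window (1982-2008).

    Returns
    -------
    xarray.Dataset
        ``monthly_mean (month, lat, lon)``, ``mmm (lat, lon)`` and
        ``overall_mean (lat, lon)``.  A pixel missing *all* observations
        of some calendar month is flagged missing (NaN) in every output,
        so it drops out of the reef analysis set downstream.
    """
    if params is None:
        params = default_params()
    if window is None:
        window = params.clim_window
    y0, y1 = window
    sel = obs.sel(time=(obs["time.year"] >= y0) & (obs["time.year"] <= y1))
    if sel.sizes["time"] == 0:
        raise ValueError(f"observations do not cover the window {y0}-{y1}")
    present = sorted(set(sel["time.month"].values.tolist()))
    if present != list(range(1, 13)):
        raise ValueError(f"window {y0}-{y1} does not cover all calendar months")

    monthly = sel.groupby("time.month").mean("time", skipna=True)
    complete = monthly.notnull().all("month")
    monthly = monthly.where(complete)
    mmm = monthly.max("month").where(complete)
    overall = monthly.mean("month").where(complete)

    ds = xr.Dataset(
        {
            "monthly_mean": monthly.rename("monthly_mean"),
            "mmm": mmm.rename("mmm"),
            "overall_mean": overall.rename("overall_mean"),
        },
        attrs={"source_window": f"{y0}-{y1}"},
    )
    ds["monthly_mean"].attrs["units"] = "degC"
    ds["mmm"].attrs["units"] = "degC"
    ds["overall_mean"].attrs["units"] = "degC"
    return ds


def compute_mmm(clim: xr.Dataset | xr.DataArray) -> xr.DataArray:
    """Maximum monthly mean: per-pixel max of the 12 monthly means."""
    monthly = clim["monthly_mean"] if isinstance(clim, xr.Dataset) else clim
    if "month" not in monthly.dims:
        raise ValueError("expected a 'month' dimension")
    return monthly.max("month").rename("mmm")
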