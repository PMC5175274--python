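"""Degree-heating thermal stress from monthly SST.

Monthly anomalies above the maximum monthly mean (MMM) are summed over
every sliding window of 3 consecutive months — degree heating months
(DHM) — and converted to degree heating weeks (DHW) with the
weeks-per-month factor 4.35.  Each window is assigned to the calendar
year of its final month (stress is realized at the end of
accumulation), and the per-year maximum over its windows gives the
annual stress series that onset detection consumes.

Only positive anomalies accumulate, as in the satellite DHW
methodology: months below MMM contribute zero, they do not offset heat.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .params import AnalysisParams, default_params

__all__ = ["window_dhm", "dhm_to_dhw", "annual_max_dhw", "annual_stress", "dhw_from_weeks"]


def window_dhm(
    series: xr.DataArray,
    mmm: xr.DataArray,
    window_months: int = 3,
) -> xr.DataArray:
    """Sliding-window degree heating months above MMM.

    Windows slide monthly across calendar-year boundaries; the value is
    labelled with the window's final month.  The first
    ``window_months - 1`` labels are NaN (incomplete windows).
    """
    if window_months < 1:
        raise ValueError("window_months must be >= 1")
    hotspot = (series - mmm).clip(min=0.0)
    dhm = hotspot.rolling(time=window_months).sum()
    return dhm.rename("dhm").assign_attrs(units="degC month")


def dhm_to_dhw(dhm, params: AnalysisParams | None = None):
    """Convert degree heating months to degree heating weeks (x 4.35)."""
    if params is None:
        params = default_params()
    arr = np.asarray(dhm.values if isinstance(dhm, xr.DataArray) else dhm)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("DHM values must be non-negative")
    out = dhm * params.dhm_to_dhw_factor
    if isinstance(out, xr.DataArray):
        out = out.rename("dhw").assign_attrs(units="DHW")
    return out


def annual_max_dhw(window_dhw: xr.DataArray, years: tuple[int, int] | None = None) -> xr.DataArray:
    """Maximum windowed DHW per calendar year.

    Windows belong to the year of their final month, so a
    December-January-February window counts toward the February year.
    The first year of a series has fewer complete windows and uses the
    ones available.
    """
    annual = window_dhw.groupby("time.year").max("time")
    if years is not None:
        y0, y1 = years
        annual = annual.sel(year=slice(y0, y1))
    return annual.rename("annual_max_dhw").assign_attrs(units="DHW")


def annual_stress(
    series: xr.DataArray,
    mmm: xr.DataArray,
    params: AnalysisParams | None = None,
) -> xr.DataArray:
    """SST series to annual maximum DHW in one step."""
    if params is None:
        params = default_params()
    dhm = window_dhm(series, mmm, params.window_months)
    dhw = dhm_to_dhw(dhm, params)
    return annual_max_dhw(dhw, params.projection_window).assign_attrs(series.attrs)


def dhw_from_weeks(excess_degc: float, weeks: float) -> float:
    """DHW accumulated by a constant exceedance above MMM for some weeks.

    One DHW is one °C above the bleaching threshold sustained for one
    week, so e.g. +2 °C held for 4 weeks accumulates 8 DHW — the severe
    bleaching stress level.
    """
    return max(0.0, float(excess_degc)) * float(weeks)
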