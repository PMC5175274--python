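"""Shared fixtures: small synthetic worlds and helper constructions.

Everything is generated programmatically; session scope keeps the more
expensive products (a full downscaled series) computed once.
"""

from __future__ import annotations

import numpy as np
import pytest
import xarray as xr

import coralclim as cc
from coralclim.grid import GridSpec, month_axis


@pytest.fixture(scope="session")
def params():
    return cc.default_params()


@pytest.fixture(scope="session")
def world():
    """Noise-free world: 3x3 coarse cells refined 4x (12x12 fine pixels)."""
    return cc.default_world(
        n_coarse_lat=3, n_coarse_lon=3, refine_factor=4, noise_sd=0.0, seed=7
    )


@pytest.fixture(scope="session")
def clim(world, params):
    cfg, coarse, fine = world
    obs = cc.synth_observed_sst(cfg, fine, params.clim_window)
    return cc.compute_monthly_climatology(obs, params.clim_window, params)


@pytest.fixture(scope="session")
def downscaled(world, clim, params):
    cfg, coarse, fine = world
    raw = cc.synth_model_sst(cfg, coarse, "rcp85", params.projection_window, "m0")
    return cc.downscale_model(raw, clim, params)


def make_clim(monthly_cycle, n_lat=1, n_lon=1):
    """Climatology dataset from a 12-value cycle (same at every pixel)."""
    g = GridSpec(np.arange(n_lat) + 0.5, np.arange(n_lon) + 100.5)
    cycle = np.asarray(monthly_cycle, dtype=float)
    monthly = xr.DataArray(
        np.broadcast_to(cycle[:, None, None], (12, n_lat, n_lon)).copy(),
        dims=("month", "lat", "lon"),
        coords={"month": np.arange(1, 13), **g.to_coords()},
        name="monthly_mean",
    )
    return xr.Dataset(
        {"monthly_mean": monthly, "mmm": monthly.max("month"),
         "overall_mean": monthly.mean("month")}
    )


def series_from_annual_anomaly(clim, anomaly_by_year, years):
    """Monthly SST = climatological cycle + a per-year (annual-step) anomaly."""
    y0, y1 = years
    t = month_axis(y0, y1)
    n_years = y1 - y0 + 1
    cycle = clim["monthly_mean"].values
    anom = np.asarray(anomaly_by_year, dtype=float)
    assert anom.size == n_years
    vals = np.tile(cycle, (n_years, 1, 1)) + np.repeat(anom, 12)[:, None, None]
    return xr.DataArray(
        vals, dims=("time", "lat", "lon"),
        coords={"time": t, "lat": clim["lat"], "lon": clim["lon"]},
        name="sst",
    )


def annual_dhw_series(values_by_year, years, n_lat=1, n_lon=1):
    """Annual-max-DHW DataArray from a per-year list (same at every pixel)."""
    y0, y1 = years
    vals = np.asarray(values_by_year, dtype=float)
    assert vals.size == y1 - y0 + 1
    g = GridSpec(np.arange(n_lat) + 0.5, np.arange(n_lon) + 100.5)
    return xr.DataArray(
        np.broadcast_to(vals[:, None, None], (vals.size, n_lat, n_lon)).copy(),
        dims=("year", "lat", "lon"),
        coords={"year": np.arange(y0, y1 + 1), **g.to_coords()},
        name="annual_max_dhw",
    )
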