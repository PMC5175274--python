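"""Synthetic SST worlds for exercising the downscaling pipeline end to end.

Real inputs to the analysis are coarse monthly SST projections from an
ensemble of global climate models and a fine (4-km class) observed
climatology.  This module fabricates both from a common "true" fine-scale
annual cycle so that every pipeline stage can be tested against known
constructions:

* the observed series is the fine cycle plus optional Gaussian noise;
* each pseudo-model sees the area mean of the fine cycle over its coarse
  cell, distorted by a model-specific mean bias and a phase shift of the
  annual cycle, plus a scenario-specific linear warming trend, noise and
  a land mask — the same nuisances the statistical downscaling removes.

`oracle_onset` computes the year of annual-severe-bleaching onset for
such a world by direct brute-force evaluation of the degree-heating
definitions, independently of the pipeline modules, and is the reference
the pipeline is compared against.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec, month_axis
from .params import AnalysisParams, default_params

__all__ = [
    "SyntheticWorldConfig",
    "default_world",
    "synth_observed_sst",
    "synth_model_sst",
    "make_reef_table",
    "oracle_onset",
]

TREND_MODES = ("annual-step", "monthly-continuous")


@dataclass
class SyntheticWorldConfig:
    """Everything needed to generate one synthetic world.

    ``base_field``, ``annual_amplitude_field`` and ``peak_month_field``
    are defined on the fine ``grid``; coarse model fields are derived
    from them by area averaging.  ``scenario_trend`` maps scenario labels
    to linear warming rates in °C/year; ``model_bias`` / ``model_phase_shift``
    map pseudo-model names to a mean offset in °C and a shift of the
    annual cycle in whole months.
    """

    grid: GridSpec
    base_field: np.ndarray
    annual_amplitude_field: np.ndarray
    peak_month_field: np.ndarray
    model_bias: dict[str, float] = field(default_factory=lambda: {"m0": 0.0})
    model_phase_shift: dict[str, int] = field(default_factory=lambda: {"m0": 0})
    scenario_trend: dict[str, float] = field(default_factory=lambda: {"rcp85": 0.032})
    trend_mode: str = "annual-step"
    noise_sd: float = 0.0
    land_mask: np.ndarray | None = None  # bool, coarse grid shape
    seed: int = 0

    def __post_init__(self) -> None:
        shape = self.grid.shape
        for name in ("base_field", "annual_amplitude_field", "peak_month_field"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                arr = np.broadcast_to(arr, shape).copy()
            setattr(self, name, arr)
        if np.any(self.annual_amplitude_field < 0):
            raise ValueError("annual_amplitude_field must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.trend_mode not in TREND_MODES:
            raise ValueError(f"trend_mode must be one of {TREND_MODES}")

    @property
    def models(self) -> list[str]:
        return list(self.model_bias)

    def fine_cycle(self) -> np.ndarray:
        """True monthly climatological cycle, shape (12, nlat, nlon)."""
        months = np.arange(1, 13)[:, None, None]
        phase = 2.0 * np.pi * (months - self.peak_month_field[None]) / 12.0
        return self.base_field[None] + self.annual_amplitude_field[None] * np.cos(phase)


def _rng(cfg: SyntheticWorldConfig, label: str) -> np.random.Generator:
    # independent, reproducible stream per product
    return np.random.default_rng([cfg.seed, zlib.crc32(label.encode())])


def _year_span(years) -> tuple[int, int]:
    if isinstance(years, range):
        if len(years) == 0:
            raise ValueError("empty year range")
        return years[0], years[-1]
    y0, y1 = int(years[0]), int(years[1])
    if y1 < y0:
        raise ValueError("year range must be non-empty")
    return y0, y1


def _series(grid: GridSpec, years, values: np.ndarray, **attrs) -> xr.DataArray:
    y0, y1 = _year_span(years)
    da = xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={"time": month_axis(y0, y1), **grid.to_coords()},
        name="sst",
        attrs={"units": "degC", **attrs},
    )
    return da


def synth_observed_sst(cfg: SyntheticWorldConfig, grid: GridSpec, years) -> xr.DataArray:
    """Monthly observed SST on the fine grid: cycle plus Gaussian noise.

    Deterministic for a fixed config seed.
    """
    if grid.n_pixels == 0:
        raise ValueError("empty grid")
    y0, y1 = _year_span(years)
    n_years = y1 - y0 + 1
    cycle = cfg.fine_cycle()
    values = np.tile(cycle, (n_years, 1, 1))
    if cfg.noise_sd > 0:
        values = values + _rng(cfg, "obs").normal(0.0, cfg.noise_sd, values.shape)
    return _series(grid, years, values, source="synthetic-observed")


def synth_model_sst(
    cfg: SyntheticWorldConfig,
    coarse_grid: GridSpec,
    scenario: str,
    years,
    model: str | None = None,
) -> xr.DataArray:
    """Monthly pseudo-GCM SST on the coarse grid for one model and scenario.

    The coarse "truth" is the area mean of the fine cycle over each
    coarse cell; on top of it the pseudo-model adds its mean bias, a
    phase-shifted annual cycle, the scenario's linear warming trend
    (stepwise per year or continuous per month, per ``cfg.trend_mode``)
    and noise.  Land-masked coarse cells are missing in all months.
    """
    if scenario not in cfg.scenario_trend:
        raise ValueError(
            f"unknown scenario {scenario!r}; configured: {sorted(cfg.scenario_trend)}"
        )
    if model is None:
        model = cfg.models[0]
    if model not in cfg.model_bias:
        raise ValueError(f"unknown model {model!r}")
    y0, y1 = _year_span(years)
    n_years = y1 - y0 + 1

    coarse_cycle = coarse_grid.block_average(cfg.fine_cycle(), cfg.grid)
    shift = int(cfg.model_phase_shift.get(model, 0))
    coarse_cycle = np.roll(coarse_cycle, shift, axis=0)

    values = np.tile(coarse_cycle, (n_years, 1, 1)) + cfg.model_bias[model]
    trend = cfg.scenario_trend[scenario]
    if cfg.trend_mode == "annual-step":
        elapsed = np.repeat(np.arange(n_years, dtype=float), 12)
    else:  # monthly-continuous
        elapsed = np.arange(12 * n_years, dtype=float) / 12.0
    values = values + trend * elapsed[:, None, None]
    if cfg.noise_sd > 0:
        values = values + _rng(cfg, f"model:{scenario}:{model}").normal(
            0.0, cfg.noise_sd, values.shape
        )
    if cfg.land_mask is not None:
        mask = np.asarray(cfg.land_mask, dtype=bool)
        if mask.shape != coarse_grid.shape:
            raise ValueError("land_mask shape does not match the coarse grid")
        values[:, mask] = np.nan
    return _series(grid=coarse_grid, years=years, values=values,
                   source="synthetic-model", model=model, scenario=scenario)


def make_reef_table(
    fine_grid: GridSpec,
    coarse_grid: GridSpec,
    n_regions: int = 3,
    fraction: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic reef-location table on the fine grid.

    Columns: ``pixel_id`` (flat fine index), ``lat``, ``lon``, ``region``
    (longitude bands standing in for country/territory labels) and
    ``coarse_id`` (flat index of the enclosing coarse cell).  ``fraction``
    subsamples pixels to mimic a sparse reef mask.
    """
    n_lat, n_lon = fine_grid.shape
    iy, ix = np.meshgrid(np.arange(n_lat), np.arange(n_lon), indexing="ij")
    pixel_id = (iy * n_lon + ix).ravel()
    lat = fine_grid.lat[iy.ravel()]
    lon = fine_grid.lon[ix.ravel()]
    coarse_id = coarse_grid.coarse_index_of(fine_grid).ravel()
    band = np.minimum((ix.ravel() * n_regions) // n_lon, n_regions - 1)
    region = np.array([f"region_{chr(ord('A') + b)}" for b in band])
    df = pd.DataFrame(
        {"pixel_id": pixel_id, "lat": lat, "lon": lon,
         "region": region, "coarse_id": coarse_id}
    )
    if fraction < 1.0:
        rng = np.random.default_rng([seed, zlib.crc32(b"reefs")])
        keep = rng.random(len(df)) < fraction
        df = df.loc[keep].reset_index(drop=True)
    return df


def default_world(
    n_coarse_lat: int = 4,
    n_coarse_lon: int = 4,
    refine_factor: int = 6,
    noise_sd: float = 0.2,
    seed: int = 0,
    trend_mode: str = "annual-step",
    scenario_trend: dict[str, float] | None = None,
    model_bias: dict[str, float] | None = None,
    model_phase_shift: dict[str, int] | None = None,
    with_land: bool = True,
) -> tuple[SyntheticWorldConfig, GridSpec, GridSpec]:
    """A small tropical world with realistic structure.

    Coarse cells are 1.5° (climate-model class), refined 6x to 0.25°
    pixels.  The base field varies smoothly both across and *within*
    coarse cells (the mechanism that creates local-scale spread in
    bleaching onset), the annual cycle has 1-3 °C amplitude with a
    February peak south of the equator and an August peak north of it,
    and the default scenario trends are RCP8.5-like (0.032 °C/yr) and
    RCP4.5-like (0.019 °C/yr) tropical-SST warming rates.

    Returns ``(config, coarse_grid, fine_grid)``.
    """
    coarse = GridSpec.regular(-3.0, 150.0, n_coarse_lat, n_coarse_lon, 1.5)
    fine = coarse.refine(refine_factor)
    lat2d, lon2d = np.meshgrid(fine.lat, fine.lon, indexing="ij")
    base = (
        27.0
        + 0.8 * np.sin(2 * np.pi * lon2d / 4.5)
        + 0.4 * np.cos(2 * np.pi * lat2d / 3.1)
        - 0.05 * np.abs(lat2d)
    )
    amplitude = 2.0 + 0.6 * np.sin(2 * np.pi * lon2d / 7.3) + 0.4 * np.cos(2 * np.pi * lat2d / 5.0)
    peak = np.where(lat2d < 0, 2, 8)
    land = None
    if with_land:
        land = np.zeros((n_coarse_lat, n_coarse_lon), dtype=bool)
        land[min(1, n_coarse_lat - 1), min(2, n_coarse_lon - 1)] = True
    cfg = SyntheticWorldConfig(
        grid=fine,
        base_field=base,
        annual_amplitude_field=amplitude,
        peak_month_field=peak,
        model_bias=model_bias or {"m0": 0.8, "m1": -0.5, "m2": 1.2},
        model_phase_shift=model_phase_shift or {"m0": 0, "m1": 1, "m2": -1},
        scenario_trend=scenario_trend or {"rcp85": 0.032, "rcp45": 0.019},
        trend_mode=trend_mode,
        noise_sd=noise_sd,
        land_mask=land,
        seed=seed,
    )
    return cfg, coarse, fine


def oracle_onset(
    clim: xr.Dataset,
    trend: float,
    params: AnalysisParams | None = None,
    trend_mode: str = "annual-step",
    baseline_centered: bool = True,
) -> np.ndarray:
    """Brute-force ASB onset for a noise-free linear-warming world.

    Evaluates, with explicit loops and no pipeline code, the full chain:
    monthly SST = climatological cycle + trend anomaly, positive
    anomalies above the maximum monthly mean summed over every sliding
    3-month window, converted to DHW, reduced to an annual maximum
    (windows assigned to the year of their last month) and scanned for
    the first ``run_length``-year run of strict threshold exceedance.

    ``baseline_centered=True`` subtracts the baseline-window mean of the
    trend anomaly first, which is what the downscaling method's
    baseline-recentering step produces for such a world; ``False``
    evaluates the raw anomaly ``trend * (year - start)``.

    Returns a float array on the climatology grid; NaN marks censored
    pixels (no qualifying run within the projection window).
    """
    if params is None:
        params = default_params()
    if trend_mode not in TREND_MODES:
        raise ValueError(f"trend_mode must be one of {TREND_MODES}")
    y0, y1 = params.projection_window
    b0, b1 = params.baseline_window
    n_years = y1 - y0 + 1
    months = [(y, m) for y in range(y0, y1 + 1) for m in range(1, 13)]

    anomaly = []
    for k, (y, m) in enumerate(months):
        if trend_mode == "annual-step":
            anomaly.append(trend * (y - y0))
        else:
            anomaly.append(trend * k / 12.0)
    if baseline_centered:
        # the cycle-substitution step removes, per calendar month, the
        # baseline-window mean of the model's series — mirror it exactly
        center = {}
        for m in range(1, 13):
            vals = [a for a, (y, mm) in zip(anomaly, months) if b0 <= y <= b1 and mm == m]
            center[m] = sum(vals) / len(vals)
        anomaly = [a - center[mm] for a, (_, mm) in zip(anomaly, months)]

    monthly = np.asarray(clim["monthly_mean"].values)  # (12, nlat, nlon)
    mmm = np.asarray(clim["mmm"].values)
    n_lat, n_lon = mmm.shape
    w = params.window_months
    onset = np.full((n_lat, n_lon), np.nan)

    for i in range(n_lat):
        for j in range(n_lon):
            if not np.isfinite(mmm[i, j]):
                continue
            sst = [monthly[m - 1, i, j] + anomaly[k] for k, (_, m) in enumerate(months)]
            hot = [max(0.0, s - mmm[i, j]) for s in sst]
            annual_max = [0.0] * n_years
            for end in range(w - 1, len(months)):
                dhw = sum(hot[end - w + 1 : end + 1]) * params.dhm_to_dhw_factor
                yi = months[end][0] - y0
                if dhw > annual_max[yi]:
                    annual_max[yi] = dhw
            run = 0
            for yi in range(n_years):
                run = run + 1 if annual_max[yi] > params.dhw_threshold else 0
                if run == params.run_length:
                    onset[i, j] = y0 + yi - params.run_length + 1
                    break
    return onset
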