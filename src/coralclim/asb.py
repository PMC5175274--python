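"""Onset of annual severe bleaching (ASB) and multi-model ensembles.

A pixel reaches ASB conditions in the first year that begins a
``run_length``-year (default 10) run in which the annual maximum DHW
strictly exceeds the threshold (default 8 DHW) every single year.  The
full run must fit inside the projection window, so the latest
admissible onset is 2090 for a 2006-2099 horizon; pixels with no
qualifying run are censored (NaN).

Per-model onset maps are combined into an equal-weight ensemble: the
mean and sample standard deviation of onset years over the models that
project an onset at that pixel.  Pixels where fewer than half the
models project an onset are censored in the ensemble.
"""

from __future__ import annotations

import warnings

import numpy as np
import xarray as xr

from .params import AnalysisParams, default_params

__all__ = ["detect_onset", "ensemble_onset"]


def detect_onset(stress: xr.DataArray, params: AnalysisParams | None = None) -> xr.DataArray:
    """First year starting a full run of annual threshold exceedance.

    Parameters
    ----------
    stress
        Annual maximum DHW, dims ``(year, lat, lon)`` (or any grid dims).

    Returns
    -------
    xarray.DataArray
        ``onset_year`` per pixel as a float; NaN where censored.
    """
    if params is None:
        params = default_params()
    run = params.run_length
    exceed = (stress > params.dhw_threshold)  # NaN compares False
    run_end = exceed.astype("f8").rolling(year=run).sum() == run
    has_run = run_end.any("year")
    first_end_idx = run_end.argmax("year")
    years = stress["year"]
    onset = years.isel(year=first_end_idx) - (run - 1)
    onset = onset.where(has_run).rename("onset_year")
    onset.attrs.update(units="year", run_length=run, dhw_threshold=params.dhw_threshold)
    for key in ("model", "scenario"):
        if key in stress.attrs:
            onset.attrs[key] = stress.attrs[key]
    return onset


def ensemble_onset(
    per_model: list[xr.DataArray],
    min_fraction: float = 0.5,
) -> xr.Dataset:
    """Equal-weight ensemble statistics over per-model onset maps.

    Censored models are excluded pixel-wise; a pixel is censored in the
    ensemble when fewer than ``min_fraction`` of the models have an
    onset there.  The spread uses the sample standard deviation (n-1),
    reported as 0 where exactly one model contributes.
    """
    if not per_model:
        raise ValueError("need at least one onset map")
    first = per_model[0]
    for om in per_model[1:]:
        if not (np.array_equal(om["lat"], first["lat"]) and np.array_equal(om["lon"], first["lon"])):
            raise ValueError("onset maps are on different grids")
    models = [om.attrs.get("model", f"m{i}") for i, om in enumerate(per_model)]
    stacked = xr.concat(per_model, dim=xr.DataArray(models, dims="model", name="model"))
    n_total = len(per_model)
    n_with = stacked.notnull().sum("model")
    keep = n_with >= max(1, int(np.ceil(min_fraction * n_total)))
    mean = stacked.mean("model", skipna=True).where(keep)
    with warnings.catch_warnings():
        # single-contributor pixels trigger a ddof warning; they are
        # assigned sd = 0 below
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = stacked.std("model", skipna=True, ddof=1)
    sd = sd.where(n_with != 1, 0.0).where(keep)
    ds = xr.Dataset(
        {
            "mean_year": mean.rename("mean_year"),
            "sd_year": sd.rename("sd_year"),
            "n_models_with_onset": n_with.rename("n_models_with_onset").astype("i4"),
        },
        attrs={"n_models_total": n_total},
    )
    if "scenario" in first.attrs:
        ds.attrs["scenario"] = first.attrs["scenario"]
    return ds
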