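"""Summary products: winner/loser classes, region statistics, scenario deltas.

Reef pixels are classified relative to the global-average onset band:
onsets before the loser cutoff (2034) are relative climate losers,
onsets after the winner cutoff (2053) are relative climate winners
("temporary refugia"), and the band in between is average.  Statistics
are aggregated per region label (country/territory stand-ins supplied
in the reef table), per coarse climate-model cell (the local-scale
variation diagnostic: latest minus earliest fine onset within a cell),
and between scenarios (RCP4.5 onset minus RCP8.5 onset, the extra years
a pixel gains under mitigation).

Censored pixels (no onset this century) are excluded from means, ranges
and percentages and reported as a separate count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .params import AnalysisParams, default_params

__all__ = [
    "classify_onset",
    "classify_onsets",
    "reef_onsets",
    "summarize_region",
    "coarse_pixel_range",
    "scenario_delta",
]

CLASSES = ("loser", "average", "winner")


def classify_onset(onset: float, params: AnalysisParams | None = None) -> str:
    """Class of a single non-censored onset year."""
    if params is None:
        params = default_params()
    if onset is None or not np.isfinite(onset):
        raise ValueError("cannot classify a censored onset; exclude censored pixels first")
    if onset < params.loser_cutoff:
        return "loser"
    if onset > params.winner_cutoff:
        return "winner"
    return "average"


def classify_onsets(onsets: np.ndarray, params: AnalysisParams | None = None) -> np.ndarray:
    """Vectorized classification; censored entries raise."""
    if params is None:
        params = default_params()
    arr = np.asarray(onsets, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot classify censored onsets; exclude censored pixels first")
    return np.select(
        [arr < params.loser_cutoff, arr > params.winner_cutoff],
        ["loser", "winner"],
        default="average",
    )


def _validate_reefs(field: xr.DataArray, reefs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    n_lat, n_lon = field.sizes["lat"], field.sizes["lon"]
    pid = reefs["pixel_id"].to_numpy()
    bad = reefs.loc[(pid < 0) | (pid >= n_lat * n_lon), "pixel_id"]
    if len(bad):
        raise ValueError(f"reef pixels outside the grid: {bad.tolist()[:10]}")
    if pid.size != np.unique(pid).size:
        raise ValueError("duplicate pixel_id entries in the reef table")
    return np.divmod(pid, n_lon)


def reef_onsets(ensemble: xr.Dataset | xr.DataArray, reefs: pd.DataFrame) -> pd.Series:
    """Ensemble mean onset year at each reef pixel (NaN = censored)."""
    field = ensemble["mean_year"] if isinstance(ensemble, xr.Dataset) else ensemble
    iy, ix = _validate_reefs(field, reefs)
    return pd.Series(field.values[iy, ix], index=reefs.index, name="onset_year")


def summarize_region(
    ensemble: xr.Dataset | xr.DataArray,
    reefs: pd.DataFrame,
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Per-region onset statistics over non-censored reef pixels.

    One row per region label: pixel counts, mean/sd/min/max/range of
    the onset year, and the percentage of pixels in each winner/loser
    class.  Regions whose pixels are all censored report ``n_pixels=0``.
    """
    if params is None:
        params = default_params()
    onsets = reef_onsets(ensemble, reefs)
    rows = []
    for region, group in reefs.assign(onset=onsets).groupby("region", sort=True):
        vals = group["onset"].dropna().to_numpy()
        n = vals.size
        row = {
            "region": region,
            "n_pixels": n,
            "n_censored": len(group) - n,
        }
        if n:
            classes = classify_onsets(vals, params)
            row.update(
                mean_onset=vals.mean(),
                sd_onset=vals.std(ddof=1) if n > 1 else 0.0,
                min_onset=vals.min(),
                max_onset=vals.max(),
                range_years=vals.max() - vals.min(),
                pct_losers=100.0 * (classes == "loser").mean(),
                pct_average=100.0 * (classes == "average").mean(),
                pct_winners=100.0 * (classes == "winner").mean(),
            )
        else:
            row.update({k: np.nan for k in (
                "mean_onset", "sd_onset", "min_onset", "max_onset", "range_years",
                "pct_losers", "pct_average", "pct_winners")})
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


def coarse_pixel_range(
    ensemble: xr.Dataset | xr.DataArray,
    reefs: pd.DataFrame,
) -> pd.DataFrame:
    """Range of fine-scale onset years within each coarse model cell.

    Latest minus earliest non-censored onset among the cell's reef
    pixels; cells with fewer than two onsets report a range of 0.  This
    is the local-scale-variation diagnostic: cells with a range over 10
    years contain both relatively early- and late-onset reefs.
    """
    onsets = reef_onsets(ensemble, reefs)
    rows = []
    for coarse_id, group in reefs.assign(onset=onsets).groupby("coarse_id", sort=True):
        vals = group["onset"].dropna().to_numpy()
        rng = float(vals.max() - vals.min()) if vals.size >= 2 else 0.0
        rows.append({"coarse_id": coarse_id, "n_onsets": vals.size, "range_years": rng})
    return pd.DataFrame(rows).set_index("coarse_id")


def scenario_delta(rcp45: xr.Dataset | xr.DataArray, rcp85: xr.Dataset | xr.DataArray) -> xr.DataArray:
    """Onset under the mitigation scenario minus under high emissions.

    Positive values are the extra years a pixel gains before annual
    severe bleaching if emissions follow the lower pathway.  Defined
    only where both scenarios have a non-censored onset.
    """
    a = rcp45["mean_year"] if isinstance(rcp45, xr.Dataset) else rcp45
    b = rcp85["mean_year"] if isinstance(rcp85, xr.Dataset) else rcp85
    if not (np.array_equal(a["lat"], b["lat"]) and np.array_equal(a["lon"], b["lon"])):
        raise ValueError("scenario onset maps are on different grids")
    delta = (a - b).where(a.notnull() & b.notnull())
    return delta.rename("delta_years").assign_attrs(
        units="years", description="RCP4.5 onset minus RCP8.5 onset"
    )
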