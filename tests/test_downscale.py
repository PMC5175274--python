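"""Downscaling chain: gap fill, regrid, cycle substitution, recentering."""

import numpy as np
import pytest
import xarray as xr

import coralclim as cc
from coralclim.downscale import model_annual_cycle
from coralclim.grid import GridSpec, month_axis


def row_da(values, lon=None):
    values = np.asarray(values, dtype=float)[None, None, :]
    n = values.shape[-1]
    lon = np.arange(n, dtype=float) if lon is None else np.asarray(lon, float)
    return xr.DataArray(
        values, dims=("time", "lat", "lon"),
        coords={"time": month_axis(2000, 2000)[:1], "lat": [0.0], "lon": lon},
    )


class TestFillZonal:
    def test_linear_midpoint(self):
        out = cc.fill_zonal(row_da([1.0, np.nan, 3.0]))
        assert np.allclose(out.values.ravel(), [1, 2, 3])

    def test_edge_nearest_interior_linear(self):
        out = cc.fill_zonal(row_da([np.nan, 2.0, np.nan, np.nan, 5.0]))
        assert np.allclose(out.values.ravel(), [2, 2, 3, 4, 5])

    def test_complete_row_unchanged(self):
        vals = [1.0, 4.0, 2.0, 8.0]
        out = cc.fill_zonal(row_da(vals))
        assert np.allclose(out.values.ravel(), vals)

    def test_all_missing_row_stays_missing(self):
        out = cc.fill_zonal(row_da([np.nan, np.nan, np.nan]))
        assert np.isnan(out.values).all()

    def test_periodic_row_interpolates_across_seam(self):
        # global 4-cell grid; gap at lon=315 sits between 225 and 45+360
        lon = np.array([45.0, 135.0, 225.0, 315.0])
        out = cc.fill_zonal(row_da([10.0, 0.0, 20.0, np.nan], lon=lon))
        assert np.isclose(out.values.ravel()[-1], 15.0)  # midpoint of 20 and 10

    def test_non_periodic_regional_grid_uses_nearest_at_edge(self):
        lon = np.array([45.0, 135.0, 225.0, 300.0])  # span < 360: regional
        out = cc.fill_zonal(row_da([10.0, 0.0, 20.0, np.nan], lon=lon))
        assert np.isclose(out.values.ravel()[-1], 20.0)


class TestRegridBilinear:
    def test_midpoint_of_four_corners(self):
        da = xr.DataArray(
            [[0.0, 0.0], [2.0, 2.0]], dims=("lat", "lon"),
            coords={"lat": [0.0, 1.0], "lon": [0.0, 1.0]},
        )
        out = cc.regrid_bilinear(da, np.array([0.5]), np.array([0.5]))
        assert np.isclose(out.values.item(), 1.0)

    def test_identity_on_same_grid(self):
        rng = np.random.default_rng(1)
        da = xr.DataArray(
            rng.normal(size=(4, 5)), dims=("lat", "lon"),
            coords={"lat": np.arange(4.0), "lon": np.arange(5.0)},
        )
        out = cc.regrid_bilinear(da, da["lat"].values, da["lon"].values)
        assert np.allclose(out.values, da.values, atol=1e-12)

    def test_matches_textbook_formula_at_random_points(self):
        rng = np.random.default_rng(5)
        lat = np.linspace(0, 6, 7)
        lon = np.linspace(10, 18, 9)
        field = rng.normal(size=(7, 9))
        da = xr.DataArray(field, dims=("lat", "lon"), coords={"lat": lat, "lon": lon})
        ty = np.sort(rng.uniform(0, 6, 100))
        tx = np.sort(rng.uniform(10, 18, 100))
        out = cc.regrid_bilinear(da, ty, tx).values
        for a, y in enumerate(ty):
            i = min(np.searchsorted(lat, y) - 1, lat.size - 2)
            i = max(i, 0)
            wy = (y - lat[i]) / (lat[i + 1] - lat[i])
            for b, x in enumerate(tx):
                j = max(min(np.searchsorted(lon, x) - 1, lon.size - 2), 0)
                wx = (x - lon[j]) / (lon[j + 1] - lon[j])
                expected = (
                    field[i, j] * (1 - wy) * (1 - wx)
                    + field[i + 1, j] * wy * (1 - wx)
                    + field[i, j + 1] * (1 - wy) * wx
                    + field[i + 1, j + 1] * wy * wx
                )
                assert abs(out[a, b] - expected) < 1e-12

    def test_outside_hull_clamps_to_edge(self):
        da = xr.DataArray(
            [[1.0, 2.0], [3.0, 4.0]], dims=("lat", "lon"),
            coords={"lat": [0.0, 1.0], "lon": [0.0, 1.0]},
        )
        out = cc.regrid_bilinear(da, np.array([-5.0]), np.array([0.0]))
        assert np.isclose(out.values.item(), 1.0)


def _baseline(series, params):
    b0, b1 = params.baseline_window
    return series.sel(time=(series["time.year"] >= b0) & (series["time.year"] <= b1))


class TestCycleAndBaseline:
    def test_identical_cycles_leave_series_unchanged(self, clim, params):
        from conftest import series_from_annual_anomaly

        anom = np.linspace(0, 2, 94)
        s = series_from_annual_anomaly(clim, anom, params.projection_window)
        cycle = model_annual_cycle(s, params.baseline_window)
        out = cc.substitute_annual_cycle(s, cycle, cycle)
        assert np.allclose(out.values, s.values, atol=1e-12)

    def test_single_month_bias_corrected_exactly(self, clim, params):
        from conftest import series_from_annual_anomaly

        s = series_from_annual_anomaly(clim, np.zeros(94), params.projection_window)
        bumped = s.where(s["time.month"] != 7, s + 1.0)
        cycle = model_annual_cycle(bumped, params.baseline_window)
        out = cc.substitute_annual_cycle(bumped, cycle, clim["monthly_mean"])
        july = out.sel(time=out["time.month"] == 7)
        ref = s.sel(time=s["time.month"] == 7)
        assert np.allclose(july.values, ref.values, atol=1e-12)

    def test_substitution_imposes_observed_cycle_in_reference_years(self, downscaled, clim, params):
        cyc = _baseline(downscaled, params).groupby("time.month").mean("time")
        diff = np.abs((cyc - clim["monthly_mean"]).values)
        assert np.nanmax(diff) < 1e-9

    def test_recenter_applies_constant_shift(self, clim, params):
        from conftest import series_from_annual_anomaly

        s = series_from_annual_anomaly(clim, np.zeros(94), params.projection_window) + 1.0
        out = cc.recenter_baseline(s, clim, params)
        assert np.allclose((s - out).values, 1.0, atol=1e-12)

    def test_recenter_preserves_linear_trend(self, clim, params):
        from conftest import series_from_annual_anomaly

        anom = 0.02 * np.arange(94)
        s = series_from_annual_anomaly(clim, anom, params.projection_window) + 0.7
        out = cc.recenter_baseline(s, clim, params)
        x = np.arange(s.sizes["time"])
        slope_in = np.polyfit(x, s.values.reshape(len(x), -1), 1)[0]
        slope_out = np.polyfit(x, out.values.reshape(len(x), -1), 1)[0]
        assert np.allclose(slope_in, slope_out, atol=1e-9)


class TestDownscaleModel:
    def test_baseline_mean_pinned_to_climatology(self, downscaled, clim, params):
        base_mean = _baseline(downscaled, params).mean("time")
        err = np.abs((base_mean - clim["overall_mean"]).values)
        assert np.nanmax(err) < 1e-6

    def test_anomalies_survive_bias_and_phase_shift(self, world, clim, params):
        """Two models differing only in bias/phase give identical output."""
        cfg, coarse, fine = world
        a = cc.synth_model_sst(cfg, coarse, "rcp85", params.projection_window, "m0")
        b = cc.synth_model_sst(cfg, coarse, "rcp85", params.projection_window, "m1")
        da = cc.downscale_model(a, clim, params)
        db = cc.downscale_model(b, clim, params)
        assert np.allclose(da.values, db.values, atol=1e-9, equal_nan=True)

    def test_anomaly_preservation(self, world, clim, downscaled, params):
        """Downscaled series minus its own baseline cycle equals the
        (pinned) model anomaly: an annual step of the scenario trend."""
        cyc = _baseline(downscaled, params).groupby("time.month").mean("time")
        anom = (downscaled.groupby("time.month") - cyc)
        trend = 0.032
        years = downscaled["time.year"].values
        expected = trend * (years - 2006) - trend * np.mean(np.arange(6))
        assert np.allclose(
            anom.values, expected[:, None, None], atol=1e-9
        )

    def test_subcoarse_structure_comes_from_climatology(self, world, clim, downscaled, params):
        """Baseline means reproduce the climatology's within-cell variation."""
        base_mean = _baseline(downscaled, params).mean("time")
        spread_down = base_mean.values.max() - base_mean.values.min()
        spread_clim = np.nanmax(clim["overall_mean"].values) - np.nanmin(clim["overall_mean"].values)
        assert spread_clim > 0.1  # the world does vary within cells
        assert np.isclose(spread_down, spread_clim, atol=1e-9)

    def test_missing_projection_years_rejected(self, world, clim, params):
        cfg, coarse, fine = world
        raw = cc.synth_model_sst(cfg, coarse, "rcp85", (2006, 2050), "m0")
        with pytest.raises(ValueError, match="does not cover"):
            cc.downscale_model(raw, clim, params)
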