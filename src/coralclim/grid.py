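"""Regular lat/lon grids and the fine-to-coarse cell mapping.

The pipeline uses two center-registered regular grids: a coarse "climate
model" grid and a fine "observation" grid whose resolution divides the
coarse resolution evenly, so every fine pixel belongs to exactly one
coarse cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

__all__ = ["GridSpec", "month_axis"]


def _check_axis(name: str, values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise ValueError(f"{name} centers must be strictly increasing")
    return arr


@dataclass(frozen=True)
class GridSpec:
    """A regular, center-registered latitude/longitude grid."""

    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lat", _check_axis("lat", self.lat))
        object.__setattr__(self, "lon", _check_axis("lon", self.lon))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    @property
    def n_pixels(self) -> int:
        return self.lat.size * self.lon.size

    @classmethod
    def regular(
        cls,
        lat0: float,
        lon0: float,
        n_lat: int,
        n_lon: int,
        res: float,
    ) -> "GridSpec":
        """Grid of ``n_lat x n_lon`` cells of size ``res`` degrees whose
        south-west cell *corner* is at ``(lat0, lon0)``."""
        lat = lat0 + res * (np.arange(n_lat) + 0.5)
        lon = lon0 + res * (np.arange(n_lon) + 0.5)
        return cls(lat, lon)

    def refine(self, factor: int) -> "GridSpec":
        """Split every cell into ``factor x factor`` fine cells."""
        if factor < 1:
            raise ValueError("refinement factor must be >= 1")
        res_lat = float(self.lat[1] - self.lat[0]) if self.lat.size > 1 else 1.0
        res_lon = float(self.lon[1] - self.lon[0]) if self.lon.size > 1 else 1.0
        off_lat = (np.arange(factor) + 0.5) / factor - 0.5
        off_lon = (np.arange(factor) + 0.5) / factor - 0.5
        lat = (self.lat[:, None] + res_lat * off_lat[None, :]).ravel()
        lon = (self.lon[:, None] + res_lon * off_lon[None, :]).ravel()
        return GridSpec(lat, lon)

    def coarse_index_of(self, fine: "GridSpec") -> np.ndarray:
        """Flat coarse-cell index of every fine pixel, shape ``fine.shape``.

        Each fine pixel is assigned to the coarse cell with the nearest
        center; grids built with :meth:`refine` map exactly.
        """
        iy = np.abs(fine.lat[:, None] - self.lat[None, :]).argmin(axis=1)
        ix = np.abs(fine.lon[:, None] - self.lon[None, :]).argmin(axis=1)
        return iy[:, None] * self.lon.size + ix[None, :]

    def block_average(self, values: np.ndarray, fine: "GridSpec") -> np.ndarray:
        """Area mean of a fine-grid field over each coarse cell.

        ``values`` has trailing dims ``fine.shape``; returns the same
        leading dims with trailing dims ``self.shape``.
        """
        idx = self.coarse_index_of(fine)
        flat = values.reshape(values.shape[:-2] + (fine.n_pixels,))
        out = np.zeros(values.shape[:-2] + (self.n_pixels,))
        counts = np.bincount(idx.ravel(), minlength=self.n_pixels)
        if np.any(counts == 0):
            raise ValueError("some coarse cells contain no fine pixels")
        np.add.at(out.reshape(-1, self.n_pixels).T, idx.ravel(), flat.reshape(-1, fine.n_pixels).T)
        out = out / counts
        return out.reshape(values.shape[:-2] + self.shape)

    def to_coords(self) -> dict[str, np.ndarray]:
        return {"lat": self.lat, "lon": self.lon}

    @classmethod
    def from_dataarray(cls, da: xr.DataArray | xr.Dataset) -> "GridSpec":
        return cls(np.asarray(da["lat"]), np.asarray(da["lon"]))


def month_axis(first_year: int, last_year: int) -> "np.ndarray":
    """Monthly ``datetime64`` axis covering Jan ``first_year`` .. Dec ``last_year``."""
    import pandas as pd

    return pd.date_range(
        start=f"{first_year}-01-01", end=f"{last_year}-12-01", freq="MS"
    ).values
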