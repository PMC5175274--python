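"""NetCDF and CSV I/O helpers.

Datasets are written as classic NetCDF (CF-style ``time``/``lat``/``lon``
dimensions) through xarray's scipy backend; 64-bit integers are
narrowed to 32-bit for classic-format compatibility.  All writes are
atomic: a temporary file in the target directory is renamed into place.
"""

from __future__ import annotations

import hashlib
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["save_dataset", "open_dataset", "save_table", "file_sha256", "atomic_path"]


class atomic_path:
    """Context manager yielding a temp path renamed to ``target`` on success."""

    def __init__(self, target: str | Path):
        self.target = Path(target)

    def __enter__(self) -> Path:
        self.target.parent.mkdir(parents=True, exist_ok=True)
        fd, tmp = tempfile.mkstemp(dir=self.target.parent, suffix=".tmp")
        os.close(fd)
        self.tmp = Path(tmp)
        return self.tmp

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            os.replace(self.tmp, self.target)
        else:
            self.tmp.unlink(missing_ok=True)


def _sanitize(ds: xr.Dataset) -> xr.Dataset:
    out = ds.copy()
    for name, var in list(out.variables.items()):
        if var.dtype == np.int64:
            out[name] = var.astype("int32")
        elif var.dtype == bool:
            out[name] = var.astype("int8")
    return out


def save_dataset(ds: xr.Dataset | xr.DataArray, path: str | Path) -> Path:
    """Write a dataset to classic NetCDF atomically."""
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset(name=ds.name or "data")
    ds = _sanitize(ds)
    encoding = {}
    if "time" in ds.coords and np.issubdtype(ds["time"].dtype, np.datetime64):
        encoding["time"] = {"dtype": "int32", "units": "days since 1900-01-01"}
    path = Path(path)
    with atomic_path(path) as tmp:
        ds.to_netcdf(tmp, engine="scipy", encoding=encoding)
    return path


def open_dataset(path: str | Path) -> xr.Dataset:
    """Read a NetCDF file (values loaded eagerly, file closed)."""
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def save_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    """Write a DataFrame to CSV atomically."""
    path = Path(path)
    with atomic_path(path) as tmp:
        df.to_csv(tmp, index=index)
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
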