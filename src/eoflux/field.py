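"""Gridded space-time fields: the package's central container and its NetCDF I/O.

A latent-heat-flux (LE) stack is stored as a ``P x N`` matrix: ``P`` spatial
pixels by ``N`` time steps, with pixels unraveled row-major from the
north-west corner of the grid (pixel ``p`` sits at grid row ``p // cols``,
column ``p % cols``). Missing data is carried as an explicit boolean mask —
not NaN alone — so the iterative gap-filling can distinguish "never
observed" from "numerically invalid".

On disk a field is a NetCDF variable with dims ``(time, y, x)``, units
``W m-2`` and a ``_FillValue`` marking missing cells. Files are written
through xarray's scipy backend (NetCDF3 classic), which keeps the format
dependency-light and plain-text-toolchain friendly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import xarray as xr

from .errors import FormatError, ValidationError

__all__ = ["SpaceTimeField", "read_field", "write_field"]

_FILL_VALUE = -9999.0


@dataclass
class SpaceTimeField:
    """A gridded space-time stack of LE values (W/m²) with a missing-data mask.

    Parameters
    ----------
    values
        ``(P, N)`` float array, P pixels by N time steps. Entries under the
        mask may hold anything (they are never read); unmasked entries must
        be finite.
    mask
        ``(P, N)`` boolean array, ``True`` where the observation is missing.
    grid_shape
        ``(rows, cols)`` with ``rows * cols == P``.
    times
        Length-``N`` strictly increasing time axis (datetime64 or numeric).
    pixel_size
        Pixel edge length in metres (default 1000 m, the 1-km product grid).
    """

    values: np.ndarray
    mask: np.ndarray
    grid_shape: tuple[int, int]
    times: np.ndarray
    pixel_size: float = 1000.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.times = np.asarray(self.times)
        self.grid_shape = (int(self.grid_shape[0]), int(self.grid_shape[1]))
        if self.values.ndim != 2:
            raise ValidationError(f"values must be 2-D (P, N), got {self.values.shape}")
        if self.mask.shape != self.values.shape:
            raise ValidationError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        rows, cols = self.grid_shape
        if rows * cols != self.values.shape[0]:
            raise ValidationError(
                f"grid_shape {self.grid_shape} inconsistent with P={self.values.shape[0]}"
            )
        if self.times.shape != (self.values.shape[1],):
            raise ValidationError(
                f"times length {self.times.shape} != N={self.values.shape[1]}"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times).astype(float) > 0):
            raise ValidationError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValidationError("non-finite values at unmasked entries")

    # -- basic introspection -------------------------------------------------

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def is_gap_free(self) -> bool:
        return not bool(self.mask.any())

    def copy(self) -> "SpaceTimeField":
        return replace(self, values=self.values.copy(), mask=self.mask.copy(),
                       times=self.times.copy())

    def with_values(self, values: np.ndarray,
                    mask: np.ndarray | None = None) -> "SpaceTimeField":
        """Same grid and time axis, new values (and optionally a new mask)."""
        if mask is None:
            mask = np.zeros_like(self.mask)
        return replace(self, values=np.asarray(values, dtype=np.float64),
                       mask=np.asarray(mask, dtype=bool))

    # -- grid <-> matrix layout ----------------------------------------------

    def to_cube(self) -> np.ndarray:
        """Return values as a ``(N, rows, cols)`` cube (NaN at masked cells)."""
        rows, cols = self.grid_shape
        cube = self.values.reshape(rows, cols, self.n_times).transpose(2, 0, 1).copy()
        mcube = self.mask.reshape(rows, cols, self.n_times).transpose(2, 0, 1)
        cube[mcube] = np.nan
        return cube

    @classmethod
    def from_cube(cls, cube: np.ndarray, times: np.ndarray,
                  pixel_size: float = 1000.0) -> "SpaceTimeField":
        """Build a field from a ``(N, rows, cols)`` cube; NaN marks missing."""
        cube = np.asarray(cube, dtype=np.float64)
        if cube.ndim != 3:
            raise ValidationError(f"cube must be 3-D (time, y, x), got {cube.shape}")
        n, rows, cols = cube.shape
        values = cube.transpose(1, 2, 0).reshape(rows * cols, n)
        mask = ~np.isfinite(values)
        values = np.where(mask, 0.0, values)
        return cls(values=values, mask=mask, grid_shape=(rows, cols),
                   times=np.asarray(times), pixel_size=pixel_size)


def write_field(field: SpaceTimeField, path: str | Path,
                variable_name: str = "LE") -> None:
    """Write a field to NetCDF with dims ``(time, y, x)`` and a ``_FillValue``."""
    rows, cols = field.grid_shape
    data = field.to_cube()  # NaN at masked cells; encoded to _FillValue below
    coords = {
        "time": field.times,
        "y": np.arange(rows, dtype=np.int32),
        "x": np.arange(cols, dtype=np.int32),
    }
    da = xr.DataArray(data, dims=("time", "y", "x"), coords=coords,
                      name=variable_name, attrs={"units": "W m-2"})
    ds = da.to_dataset()
    ds.attrs["pixel_size_m"] = float(field.pixel_size)
    encoding: dict = {variable_name: {"_FillValue": _FILL_VALUE}}
    if np.issubdtype(field.times.dtype, np.datetime64):
        # NetCDF3 has no int64; force a float time encoding
        encoding["time"] = {"units": "days since 1970-01-01", "dtype": "float64"}
    else:
        ds["time"] = ds["time"].astype(np.float64)
    ds.to_netcdf(path, engine="scipy", encoding=encoding)


def read_field(path: str | Path, variable_name: str = "LE") -> SpaceTimeField:
    """Read a ``(time, y, x)`` NetCDF variable into a :class:`SpaceTimeField`.

    The mask marks exactly the fill-valued entries. Raises
    :class:`FormatError` if the variable is absent and
    :class:`ValidationError` if the time axis is not strictly increasing.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable_name not in ds.variables:
            raise FormatError(
                f"variable {variable_name!r} not found in {path}; "
                f"available: {sorted(ds.data_vars)}"
            )
        da = ds[variable_name]
        if da.ndim != 3:
            raise FormatError(f"variable {variable_name!r} must be 3-D (time, y, x)")
        times = np.asarray(ds["time"].values)
        pixel_size = float(ds.attrs.get("pixel_size_m", 1000.0))
        cube = np.asarray(da.values, dtype=np.float64)
    if times.size > 1 and not np.all(np.diff(times).astype(float) > 0):
        raise ValidationError(f"time axis in {path} is not strictly increasing")
    return SpaceTimeField.from_cube(cube, times=times, pixel_size=pixel_size)
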