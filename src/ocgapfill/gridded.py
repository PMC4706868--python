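"""Daily gridded fields on a regular latitude/longitude grid.

A :class:`GriddedDataset` wraps an :class:`xarray.Dataset` with dimensions
``(time, lat, lon)`` and the variable dialect the pipeline speaks:

    chlor_a           chlorophyll-a, mg/m^3 (the target; NaN = gap)
    ssh, sss, sst     surface predictors (m, g/kg, degC)
    sal_1..sal_7      upper-ocean salinity profile, g/kg (level 1 shallowest)
    temp_1..temp_7    upper-ocean temperature profile, degC
    land              1 on land cells, 0 on ocean (int8, (lat, lon))
    chla_true         noise-free target, synthetic data only
    chlor_a_filled    gap-filled product (after fill_gaps)
    provenance        0 observed / 1 filled / 2 unfillable / 3 land (int8)

Validity is encoded as NaN; per-variable boolean masks are derived on demand.
The ``time`` coordinate is an integer day index with ``year`` and
``day_of_year`` auxiliary coordinates, so a synthetic calendar (365-day
years) and a real calendar can both be represented.  NetCDF I/O uses the
classic (netCDF3) format via xarray's scipy backend.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .features import PREDICTOR_NAMES

__all__ = ["GriddedDataset", "PROVENANCE"]

#: provenance codes in the gap-filled product
PROVENANCE = {"observed": 0, "filled": 1, "unfillable": 2, "land": 3}


@dataclass
class GriddedDataset:
    data: xr.Dataset

    def __post_init__(self) -> None:
        for dim in ("time", "lat", "lon"):
            if dim not in self.data.dims:
                raise ValueError(f"dataset lacks dimension {dim!r}")
        for coord in ("year", "day_of_year"):
            if coord not in self.data.coords:
                raise ValueError(f"dataset lacks coordinate {coord!r}")
        shape = (self.data.sizes["time"], self.data.sizes["lat"], self.data.sizes["lon"])
        for name, var in self.data.data_vars.items():
            if name in ("land",):
                continue
            if var.dims != ("time", "lat", "lon"):
                raise ValueError(f"variable {name!r} has dims {var.dims}")
            if var.shape != shape:
                raise ValueError(f"variable {name!r} has shape {var.shape} != {shape}")

    # -- axes -------------------------------------------------------------
    @property
    def lat(self) -> np.ndarray:
        return self.data["lat"].to_numpy()

    @property
    def lon(self) -> np.ndarray:
        return self.data["lon"].to_numpy()

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def year(self) -> np.ndarray:
        return self.data["year"].to_numpy()

    @property
    def day_of_year(self) -> np.ndarray:
        return self.data["day_of_year"].to_numpy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.time), len(self.lat), len(self.lon))

    # -- masks ------------------------------------------------------------
    @property
    def ocean_mask(self) -> np.ndarray:
        """(lat, lon) boolean, True on ocean cells."""
        if "land" in self.data:
            return self.data["land"].to_numpy() == 0
        return np.ones((len(self.lat), len(self.lon)), dtype=bool)

    def valid_mask(self, var: str) -> np.ndarray:
        """(time, lat, lon) boolean validity mask for one variable."""
        return np.isfinite(self.data[var].to_numpy())

    def complete_predictor_mask(self) -> np.ndarray:
        """(time, lat, lon) True where all 17 physical predictors are valid."""
        mask = np.broadcast_to(self.ocean_mask, self.shape).copy()
        for name in PREDICTOR_NAMES:
            mask &= self.valid_mask(name)
        return mask

    # -- I/O ---------------------------------------------------------------
    def to_netcdf(self, path: str | Path) -> None:
        """Write as classic NetCDF (scipy backend; no netCDF4 needed)."""
        self.data.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "GriddedDataset":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls(ds.load())

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a long record table (time-major, then lat, then lon)."""
        T, I, J = self.shape
        tt, ii, jj = np.meshgrid(np.arange(T), np.arange(I), np.arange(J), indexing="ij")
        out = pd.DataFrame(
            {
                "time": self.time[tt.ravel()],
                "year": self.year[tt.ravel()],
                "day_of_year": self.day_of_year[tt.ravel()],
                "lat": self.lat[ii.ravel()],
                "lon": self.lon[jj.ravel()],
            }
        )
        for name, var in self.data.data_vars.items():
            if name == "land":
                out[name] = np.broadcast_to(var.to_numpy(), (T, I, J)).ravel()
            else:
                out[name] = var.to_numpy().ravel()
        return out

    @staticmethod
    def build(
        time: np.ndarray,
        year: np.ndarray,
        day_of_year: np.ndarray,
        lat: np.ndarray,
        lon: np.ndarray,
        variables: dict[str, np.ndarray],
        land: np.ndarray | None = None,
        attrs: dict | None = None,
    ) -> "GriddedDataset":
        coords = {
            "time": ("time", np.asarray(time)),
            "year": ("time", np.asarray(year)),
            "day_of_year": ("time", np.asarray(day_of_year)),
            "lat": ("lat", np.asarray(lat, dtype=float)),
            "lon": ("lon", np.asarray(lon, dtype=float)),
        }
        data_vars = {
            name: (("time", "lat", "lon"), np.asarray(arr, dtype=float))
            for name, arr in variables.items()
        }
        if land is not None:
            data_vars["land"] = (("lat", "lon"), np.asarray(land, dtype=np.int8))
        ds = xr.Dataset(data_vars, coords=coords, attrs=attrs or {})
        return GriddedDataset(ds)
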