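"""Build the 23-component predictor vector and standardize it for training.

Each record pairs one grid point on one day with a chlorophyll-a value.  The
input vector concatenates six metadata components with seventeen physical
predictors, in this fixed order:

    1       year                      (raw calendar year)
    2-3     sin/cos(2*pi*day/D)       (cyclical day-of-year, D = 365 or 366)
    4-5     sin/cos(lon)              (cyclical longitude, radians)
    6       sin(lat)                  (latitude, radians; sine only)
    7       SSH  (m)
    8       SSS  (g/kg)
    9       SST  (degC)
    10-16   salinity profile, 7 upper-ocean levels (g/kg)
    17-23   temperature profile, 7 upper-ocean levels (degC)

The cyclical encodings let a single global network see that day 366 abuts
day 1 and longitude -180 abuts +180.  Latitude is encoded with its sine only.
Profile levels are positional (level 1 shallowest, level 7 deepest, top 75 m).

Inputs and the target are z-scored with constants fitted on the training set;
predictions are mapped back to mg/m^3 with the target's own constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "INPUT_NAMES",
    "N_INPUTS",
    "PREDICTOR_NAMES",
    "RawRecord",
    "EncodedRecord",
    "Standardizer",
    "encode_record",
    "encode_frame",
    "fit_standardizer",
    "read_record_csv",
    "write_record_csv",
]

SAL_NAMES = [f"sal_{i}" for i in range(1, 8)]
TEMP_NAMES = [f"temp_{i}" for i in range(1, 8)]
#: the 17 physical predictors a record must carry to be usable
PREDICTOR_NAMES = ["ssh", "sss", "sst", *SAL_NAMES, *TEMP_NAMES]
#: the 23 network inputs, in order
INPUT_NAMES = ["year", "day_sin", "day_cos", "lon_sin", "lon_cos", "lat_sin", *PREDICTOR_NAMES]
N_INPUTS = len(INPUT_NAMES)
#: identifier columns carried through the flat-CSV record dialect
ID_NAMES = ["time", "lat", "lon"]
TARGET_NAME = "chla"


@dataclass
class RawRecord:
    """One grid-point/day observation before encoding."""

    year: int
    day_of_year: int
    lon: float  # degrees east, [-180, 360) accepted
    lat: float  # degrees north
    ssh: float
    sss: float
    sst: float
    sal_profile: np.ndarray  # 7 levels, g/kg
    temp_profile: np.ndarray  # 7 levels, degC
    chla: float | None = None  # mg/m^3, None/NaN = missing

    def __post_init__(self) -> None:
        self.sal_profile = np.asarray(self.sal_profile, dtype=float)
        self.temp_profile = np.asarray(self.temp_profile, dtype=float)
        if not 1 <= self.day_of_year <= 366:
            raise ValueError(f"day_of_year {self.day_of_year} outside 1..366")
        if not -90 <= self.lat <= 90:
            raise ValueError(f"lat {self.lat} outside [-90, 90]")
        if not -180 <= self.lon < 360:
            raise ValueError(f"lon {self.lon} outside [-180, 360)")
        if self.sal_profile.shape != (7,) or self.temp_profile.shape != (7,):
            raise ValueError("profiles must have exactly 7 levels")


@dataclass
class EncodedRecord:
    """The 23-vector ``x`` plus target and identifiers."""

    x: np.ndarray
    y: float  # NaN when the target is missing
    lat: float
    lon: float


def normalize_lon(lon):
    """Map longitudes to [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def encode_record(raw: RawRecord, day_denominator: int = 366) -> EncodedRecord:
    """Encode one raw record into the 23-component input vector."""
    tau = 2.0 * np.pi * raw.day_of_year / day_denominator
    lon = np.deg2rad(normalize_lon(raw.lon))
    lat = np.deg2rad(raw.lat)
    x = np.concatenate(
        [
            [float(raw.year), np.sin(tau), np.cos(tau), np.sin(lon), np.cos(lon), np.sin(lat)],
            [raw.ssh, raw.sss, raw.sst],
            raw.sal_profile,
            raw.temp_profile,
        ]
    )
    y = np.nan if raw.chla is None else float(raw.chla)
    return EncodedRecord(x=x, y=y, lat=raw.lat, lon=raw.lon)


def encode_frame(records: pd.DataFrame, day_denominator: int = 366) -> pd.DataFrame:
    """Vectorized encoding of a table of raw records.

    ``records`` needs columns ``year, day_of_year, lon, lat`` plus the 17
    predictors; ``chla`` and identifier columns are carried through when
    present.  Returns a frame with the 23 ``INPUT_NAMES`` columns in order.
    """
    req = ["year", "day_of_year", "lon", "lat", *PREDICTOR_NAMES]
    missing = [c for c in req if c not in records.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    tau = 2.0 * np.pi * records["day_of_year"].to_numpy(float) / day_denominator
    lon = np.deg2rad(normalize_lon(records["lon"].to_numpy(float)))
    lat = np.deg2rad(records["lat"].to_numpy(float))
    out = pd.DataFrame(index=records.index)
    for col in ("time", "lat", "lon"):
        if col in records.columns:
            out[col] = records[col]
    out["year"] = records["year"].to_numpy(float)
    out["day_sin"] = np.sin(tau)
    out["day_cos"] = np.cos(tau)
    out["lon_sin"] = np.sin(lon)
    out["lon_cos"] = np.cos(lon)
    out["lat_sin"] = np.sin(lat)
    for col in PREDICTOR_NAMES:
        out[col] = records[col].to_numpy(float)
    if TARGET_NAME in records.columns:
        out[TARGET_NAME] = records[TARGET_NAME].to_numpy(float)
    return out


@dataclass
class Standardizer:
    """Per-input z-scoring constants fitted on training data.

    The target keeps its own ``(y_mean, y_scale)`` pair so network outputs can
    be mapped back to mg/m^3.  Constant columns get scale 1 (with a warning at
    fit time) so they standardize to exactly zero.
    """

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float

    def transform_x(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.x_mean) / self.x_scale

    def inverse_x(self, xs: np.ndarray) -> np.ndarray:
        return np.asarray(xs, dtype=float) * self.x_scale + self.x_mean

    def transform_y(self, y):
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_scale

    def inverse_y(self, ys):
        return np.asarray(ys, dtype=float) * self.y_scale + self.y_mean

    def to_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(
            np.array(d["x_mean"], dtype=float),
            np.array(d["x_scale"], dtype=float),
            float(d["y_mean"]),
            float(d["y_scale"]),
        )


def _safe_scale(std: np.ndarray, what: str) -> np.ndarray:
    std = np.atleast_1d(np.asarray(std, dtype=float)).copy()
    bad = std == 0.0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} constant {what} column(s); scale forced to 1",
            stacklevel=3,
        )
        std[bad] = 1.0
    return std


def fit_standardizer(x: np.ndarray, y: np.ndarray | None = None) -> Standardizer:
    """Fit per-column mean/std (population std) on training data; >= 2 rows."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("need at least 2 records to fit a standardizer")
    x_mean = x.mean(axis=0)
    x_scale = _safe_scale(x.std(axis=0), "input")
    if y is None:
        y_mean, y_scale = 0.0, 1.0
    else:
        y = np.asarray(y, dtype=float).ravel()
        y_mean = float(np.mean(y))
        y_scale = float(_safe_scale(np.array([np.std(y)]), "target")[0])
    return Standardizer(x_mean, x_scale, y_mean, y_scale)


# ---------------------------------------------------------------------------
# flat CSV record dialect: 3 identifiers + 23 inputs + target = 27 columns

CSV_COLUMNS = [*ID_NAMES, *INPUT_NAMES, TARGET_NAME]


def write_record_csv(path, encoded: pd.DataFrame) -> None:
    """Write encoded records as the documented 27-column CSV."""
    missing = [c for c in CSV_COLUMNS if c not in encoded.columns]
    if missing:
        raise ValueError(f"encoded frame lacks columns {missing}")
    encoded.to_csv(path, columns=CSV_COLUMNS, index=False)


def read_record_csv(path) -> pd.DataFrame:
    """Read the 27-column record CSV back into a DataFrame."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: lacks columns {missing}")
    return df[CSV_COLUMNS]
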