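"""Core containers for weekly gridded fields and climate-index series.

The analysis runs on a 52-week composite calendar: every year contributes
exactly 52 weekly composites (week 1..52, day 365/366 dropped), so the time
axis of a :class:`WeeklyCube` is uniform by construction and climatology can
be keyed to the calendar week.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import xarray as xr

WEEKS_PER_YEAR = 52

#: recognised variable tags and their physical ranges (None = unbounded)
VARIABLE_TAGS = {
    "NDVI": (-1.0, 1.0),
    "BT": (None, None),
    "SMN": (-1.0, 1.0),
    "SMT": (None, None),
    "VCI": (0.0, 100.0),
    "TCI": (0.0, 100.0),
    "VHI": (0.0, 100.0),
}


def week_start_date(year: int, week: int) -> _dt.date:
    """First day of composite `week` (1..52) of `year`."""
    return _dt.date(int(year), 1, 1) + _dt.timedelta(days=7 * (int(week) - 1))


@dataclass
class WeeklyCube:
    """A (time, lat, lon) gridded weekly field with a validity mask.

    Parameters
    ----------
    values : float array, shape (n_time, n_lat, n_lon)
    year, week : int arrays, shape (n_time,); week in 1..52
    mask : bool array, same shape as values; True marks a valid cell
    tag : variable tag, one of ``VARIABLE_TAGS``
    lat, lon : optional coordinate vectors (degrees, centre of cell)
    """

    values: np.ndarray
    year: np.ndarray
    week: np.ndarray
    mask: np.ndarray | None = None
    tag: str = "NDVI"
    lat: np.ndarray | None = None
    lon: np.ndarray | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (time, lat, lon)")
        nt = self.values.shape[0]
        self.year = np.asarray(self.year, dtype=int)
        self.week = np.asarray(self.week, dtype=int)
        if self.year.shape != (nt,) or self.week.shape != (nt,):
            raise ValueError("year/week must be 1-D of length n_time")
        if self.week.min() < 1 or self.week.max() > WEEKS_PER_YEAR:
            raise ValueError("calendar week must be in 1..52")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")
        gw = self.global_week
        if nt > 1 and not np.all(np.diff(gw) == 1):
            gaps = gw[:-1][np.diff(gw) != 1] + 1
            missing = [
                f"{g // WEEKS_PER_YEAR + self.year[0]}-W{g % WEEKS_PER_YEAR + 1:02d}"
                for g in gaps
            ]
            raise ValueError(
                "time axis is not a uniform weekly sequence; first missing "
                f"weeks: {missing[:5]}"
            )
        if self.tag not in VARIABLE_TAGS:
            raise ValueError(f"unknown variable tag {self.tag!r}")
        if self.lat is not None:
            self.lat = np.asarray(self.lat, dtype=float)
        if self.lon is not None:
            self.lon = np.asarray(self.lon, dtype=float)

    # -- basic geometry -------------------------------------------------
    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def global_week(self) -> np.ndarray:
        """0-based week index counted from week 1 of the first year."""
        return (self.year - self.year[0]) * WEEKS_PER_YEAR + (self.week - 1)

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.year)

    @property
    def time_years(self) -> np.ndarray:
        """Time in fractional years since the record start (for trends)."""
        return self.global_week / WEEKS_PER_YEAR

    def dates(self) -> list[_dt.date]:
        return [week_start_date(y, w) for y, w in zip(self.year, self.week)]

    # -- values ---------------------------------------------------------
    def masked_values(self) -> np.ndarray:
        """Values with invalid cells replaced by NaN (a copy)."""
        out = self.values.astype(float).copy()
        out[~self.mask] = np.nan
        return out

    def regional_mean(self) -> np.ndarray:
        """Area mean over valid pixels per time step (NaN where none valid)."""
        v = self.masked_values().reshape(self.n_time, -1)
        valid = np.isfinite(v)
        n = valid.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(valid, v, 0.0).sum(axis=1) / np.where(
                n > 0, n, np.nan)

    def with_values(self, values: np.ndarray, tag: str | None = None,
                    mask: np.ndarray | None = None) -> "WeeklyCube":
        """New cube sharing this cube's axes."""
        return WeeklyCube(
            values=values,
            year=self.year.copy(),
            week=self.week.copy(),
            mask=self.mask.copy() if mask is None else mask,
            tag=self.tag if tag is None else tag,
            lat=None if self.lat is None else self.lat.copy(),
            lon=None if self.lon is None else self.lon.copy(),
            attrs=dict(self.attrs),
        )

    def aligned_with(self, other: "WeeklyCube") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.array_equal(self.year, other.year)
            and np.array_equal(self.week, other.week)
        )

    # -- xarray / NetCDF round trip --------------------------------------
    def to_dataset(self) -> xr.Dataset:
        nt, ny, nx = self.values.shape
        lat = self.lat if self.lat is not None else np.arange(ny, dtype=float)
        lon = self.lon if self.lon is not None else np.arange(nx, dtype=float)
        time = pd.to_datetime([week_start_date(y, w)
                               for y, w in zip(self.year, self.week)])
        da = xr.DataArray(
            self.masked_values(),
            dims=("time", "lat", "lon"),
            coords={"time": time, "lat": lat, "lon": lon},
            name=self.tag,
            attrs={"units": _units_for(self.tag), **{
                k: v for k, v in self.attrs.items()
                if isinstance(v, (int, float, str))}},
        )
        ds = da.to_dataset()
        ds = ds.assign_coords(
            year=("time", self.year.astype("int32")),
            week=("time", self.week.astype("int32")),
        )
        ds.attrs["variable_tag"] = self.tag
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset, tag: str | None = None) -> "WeeklyCube":
        if tag is None:
            tag = ds.attrs.get("variable_tag") or list(ds.data_vars)[0]
        da = ds[tag]
        if "year" in ds.coords and "week" in ds.coords:
            year = np.asarray(ds["year"].values, dtype=int)
            week = np.asarray(ds["week"].values, dtype=int)
        else:
            times = pd.to_datetime(da["time"].values)
            year = times.year.to_numpy()
            week = np.clip(times.dayofyear.to_numpy() // 7 + 1, 1, WEEKS_PER_YEAR)
        values = np.asarray(da.values, dtype=float)
        return cls(
            values=values,
            year=year,
            week=week,
            mask=np.isfinite(values),
            tag=tag,
            lat=np.asarray(da["lat"].values, dtype=float),
            lon=np.asarray(da["lon"].values, dtype=float),
        )


def _units_for(tag: str) -> str:
    if tag in ("BT", "SMT"):
        return "degC"
    if tag in ("VCI", "TCI", "VHI"):
        return "index_0_100"
    return "unitless"


@dataclass
class ClimateIndexSeries:
    """A uniform weekly (or monthly) climate-index series, e.g. Niño 3.4."""

    values: np.ndarray
    year: np.ndarray | None = None
    week: np.ndarray | None = None
    name: str = "nino34"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("index series must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("index series must be finite")
        if self.year is not None:
            self.year = np.asarray(self.year, dtype=int)
            self.week = np.asarray(self.week, dtype=int)
            if self.year.shape != self.values.shape:
                raise ValueError("year axis length mismatch")

    def __len__(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        if self.year is None:
            return pd.DataFrame({"value": self.values})
        dates = [week_start_date(y, w) for y, w in zip(self.year, self.week)]
        return pd.DataFrame({"iso_week_start_date": dates, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, name: str = "index") -> "ClimateIndexSeries":
        df = pd.read_csv(path)
        if "iso_week_start_date" in df.columns:
            dates = pd.to_datetime(df["iso_week_start_date"])
            year = dates.dt.year.to_numpy()
            week = np.clip(dates.dt.dayofyear.to_numpy() // 7 + 1, 1,
                           WEEKS_PER_YEAR)
            return cls(df["value"].to_numpy(float), year, week, name=name)
        return cls(df["value"].to_numpy(float), name=name)


def weekly_axis(start_year: int, n_years: int) -> tuple[np.ndarray, np.ndarray]:
    """(year, week) vectors for `n_years` complete 52-week years."""
    years = np.repeat(np.arange(start_year, start_year + n_years), WEEKS_PER_YEAR)
    weeks = np.tile(np.arange(1, WEEKS_PER_YEAR + 1), n_years)
    return years, weeks
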