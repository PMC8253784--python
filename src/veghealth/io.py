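"""Readers and writers: NetCDF cubes, per-week TIFF directories, CSV series.

NetCDF goes through xarray's scipy backend (NetCDF-3 classic, CF-style
time/lat/lon dims, NaN fill for masked cells). A directory of per-week
single-band TIFFs with names like ``NDVI_1985_w07.tif`` is accepted as an
alternative ingest format (plain TIFF rasters; georeferencing is carried
in the NetCDF route).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import xarray as xr

from .cube import WEEKS_PER_YEAR, WeeklyCube

_TIFF_NAME = re.compile(r"(?P<tag>[A-Za-z]+)_(?P<year>\d{4})_w(?P<week>\d{1,2})"
                        r"\.tiff?$")


def write_cube(cube: WeeklyCube, path: str | Path) -> Path:
    path = Path(path)
    cube.to_dataset().to_netcdf(path, engine="scipy")
    return path


def read_cube(path: str | Path, variable_tag: str | None = None) -> WeeklyCube:
    """Read a WeeklyCube from NetCDF or a directory of per-week TIFFs.

    The time axis must be a gapless weekly sequence; a missing week
    raises a ValueError naming the gap.
    """
    path = Path(path)
    if path.is_dir():
        return _read_tiff_dir(path, variable_tag)
    with xr.open_dataset(path, engine="scipy") as ds:
        return WeeklyCube.from_dataset(ds.load(), tag=variable_tag)


def _read_tiff_dir(path: Path, variable_tag: str | None) -> WeeklyCube:
    import tifffile

    entries = []
    for f in sorted(path.iterdir()):
        m = _TIFF_NAME.match(f.name)
        if not m:
            continue
        if variable_tag and m.group("tag") != variable_tag:
            continue
        entries.append((int(m.group("year")), int(m.group("week")),
                        m.group("tag"), f))
    if not entries:
        raise ValueError(f"no parseable <TAG>_<year>_w<week>.tif files in "
                         f"{path}")
    entries.sort(key=lambda e: (e[0], e[1]))
    tag = variable_tag or entries[0][2]
    year = np.array([e[0] for e in entries])
    week = np.array([e[1] for e in entries])
    gw = (year - year[0]) * WEEKS_PER_YEAR + week - 1
    if np.any(np.diff(gw) != 1):
        i = int(np.flatnonzero(np.diff(gw) != 1)[0])
        miss_gw = gw[i] + 1
        raise ValueError(
            "weekly TIFF sequence has a gap; first missing week: "
            f"{year[0] + miss_gw // WEEKS_PER_YEAR}-W"
            f"{miss_gw % WEEKS_PER_YEAR + 1:02d}")
    values = np.stack([tifffile.imread(e[3]).astype(float) for e in entries])
    return WeeklyCube(values, year, week, np.isfinite(values), tag=tag)


def write_tiff_dir(cube: WeeklyCube, path: str | Path) -> Path:
    """Write one float32 TIFF per week, named ``<TAG>_<year>_w<week>.tif``."""
    import tifffile

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    v = cube.masked_values().astype(np.float32)
    for i, (y, w) in enumerate(zip(cube.year, cube.week)):
        tifffile.imwrite(path / f"{cube.tag}_{y}_w{w:02d}.tif", v[i])
    return path


def write_extrema(extrema, path: str | Path) -> Path:
    """Per-pixel climatology extrema as a 4-variable NetCDF."""
    ds = xr.Dataset(
        {
            f"{extrema.tag.lower()}_max": (("week", "lat", "lon"),
                                           extrema.vmax),
            f"{extrema.tag.lower()}_min": (("week", "lat", "lon"),
                                           extrema.vmin),
            "degenerate": (("week", "lat", "lon"),
                           extrema.degenerate.astype("int8")),
        },
        coords={"week": np.arange(1, WEEKS_PER_YEAR + 1)},
        attrs={"per_week": int(extrema.per_week), "variable_tag": extrema.tag},
    )
    ds.to_netcdf(path, engine="scipy")
    return Path(path)
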