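"""Forcing I/O: grids, the 8-day compositing calendar, NetCDF read/write,
and regridding of heterogeneous-resolution inputs onto the analysis grid.

Conventions
-----------
* Regular geographic (lat/lon) grids, cell-center registration, latitude
  stored descending (north to south) in files; ascending input is accepted
  and normalized on read.
* The temporal axis is the MODIS-style 8-day compositing calendar: 46
  periods per year starting at day-of-year 1, 9, ..., 361; the final period
  is 5 days (6 in leap years).
* Missing data are NaN in memory and ``_FillValue = -9999.0`` on disk.
* Relative humidity is a fraction in [0, 1] in memory; files in percent
  (detected by max > 1.5) are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr

from .ptjpl import FILL_VALUE

__all__ = [
    "GridSpec",
    "CompositingCalendar",
    "ForcingFields",
    "ForcingFormatError",
    "CalendarError",
    "LANDCOVER_CODES",
    "LANDCOVER_NAMES",
    "VEGETATED_CLASSES",
    "NONVEG",
    "read_forcing",
    "write_forcing",
    "regrid",
    "composite_to_8day",
]

#: Integer codes for the land-cover classification.
LANDCOVER_CODES = {"nonveg": 0, "forest": 1, "shrub": 2, "grass": 3, "crop": 4}
LANDCOVER_NAMES = {v: k for k, v in LANDCOVER_CODES.items()}
VEGETATED_CLASSES = ("forest", "shrub", "grass", "crop")
NONVEG = LANDCOVER_CODES["nonveg"]

FORCING_VARS = ("lai", "rn", "ta", "rh", "g")


class ForcingFormatError(ValueError):
    """A forcing file is missing required coordinates or metadata."""


class CalendarError(ValueError):
    """A daily series does not match the compositing calendar."""


@dataclass(frozen=True)
class GridSpec:
    """A regular lat/lon grid, cell-center registered.

    ``n_lat``/``n_lon`` are derived from the bounds and cell size; latitude
    centers run north to south (descending), longitude west to east.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    cell_size: float = 0.05

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid must contain at least one cell per axis")

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.cell_size))

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.cell_size))

    @property
    def lats(self) -> np.ndarray:
        """Latitude cell centers, descending (N -> S)."""
        return self.lat_max - (np.arange(self.n_lat) + 0.5) * self.cell_size

    @property
    def lons(self) -> np.ndarray:
        """Longitude cell centers, ascending (W -> E)."""
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.cell_size

    @property
    def lat_edges(self) -> np.ndarray:
        """Latitude cell edges, ascending (for overlap arithmetic)."""
        return self.lat_min + np.arange(self.n_lat + 1) * self.cell_size

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon_min + np.arange(self.n_lon + 1) * self.cell_size

    @classmethod
    def from_coords(cls, lats, lons) -> "GridSpec":
        """Infer a GridSpec from cell-center coordinate arrays."""
        lats = np.asarray(lats, float)
        lons = np.asarray(lons, float)
        if lats.size < 1 or lons.size < 1:
            raise ForcingFormatError("empty coordinate arrays")
        dlat = abs(lats[1] - lats[0]) if lats.size > 1 else (
            abs(lons[1] - lons[0]) if lons.size > 1 else 0.05
        )
        dlon = abs(lons[1] - lons[0]) if lons.size > 1 else dlat
        if not np.isclose(dlat, dlon):
            raise ForcingFormatError("anisotropic cells are not supported")
        return cls(
            lat_min=float(lats.min() - dlat / 2),
            lat_max=float(lats.max() + dlat / 2),
            lon_min=float(lons.min() - dlon / 2),
            lon_max=float(lons.max() + dlon / 2),
            cell_size=float(dlat),
        )


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


@dataclass(frozen=True)
class CompositingCalendar:
    """The 46-period 8-day compositing calendar for one year.

    Periods start at day-of-year 1, 9, ..., 361; periods 1-45 are 8 days
    long, period 46 covers the remaining 5 (or 6, leap year) days.
    """

    year: int

    @property
    def period_starts(self) -> np.ndarray:
        return np.arange(1, 362, 8)

    @property
    def period_lengths(self) -> np.ndarray:
        lengths = np.full(46, 8, dtype=int)
        lengths[-1] = 6 if _is_leap(self.year) else 5
        return lengths

    @property
    def n_periods(self) -> int:
        return 46

    @property
    def days_in_year(self) -> int:
        return 366 if _is_leap(self.year) else 365

    @property
    def period_ends(self) -> np.ndarray:
        return self.period_starts + self.period_lengths - 1


@dataclass
class ForcingFields:
    """Co-registered gridded forcing for one or more years.

    Time axis is ``46 * len(years)`` compositing periods; spatial axes
    follow ``grid`` (lat descending).  Missing forcing is NaN.  ``g``
    (ground heat flux) defaults to zero everywhere; at the 8-day scale soil
    heat storage is negligible, but a layer may be supplied to override.
    """

    grid: GridSpec
    years: tuple[int, ...]
    lai: np.ndarray
    rn: np.ndarray
    ta: np.ndarray
    rh: np.ndarray
    landcover: np.ndarray
    g: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        shape = (46 * len(self.years), self.grid.n_lat, self.grid.n_lon)
        for name in ("lai", "rn", "ta", "rh"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        if self.g is None:
            self.g = np.zeros(shape)
        else:
            self.g = np.asarray(self.g, float)
            if self.g.shape != shape:
                raise ValueError("g layer shape mismatch")
        self.landcover = np.asarray(self.landcover)
        if self.landcover.shape != shape[1:]:
            raise ValueError("landcover shape mismatch")
        valid_rh = self.rh[np.isfinite(self.rh)]
        if valid_rh.size and (valid_rh.min() < 0 or valid_rh.max() > 1):
            raise ValueError("rh must be a fraction in [0, 1]")
        valid_lai = self.lai[np.isfinite(self.lai)]
        if valid_lai.size and valid_lai.min() < 0:
            raise ValueError("lai must be >= 0")

    @property
    def calendars(self) -> tuple[CompositingCalendar, ...]:
        return tuple(CompositingCalendar(y) for y in self.years)

    @property
    def n_time(self) -> int:
        return 46 * len(self.years)

    @property
    def period_lengths(self) -> np.ndarray:
        """Days in each period along the whole time axis."""
        return np.concatenate([c.period_lengths for c in self.calendars])

    @property
    def period_starts(self) -> np.ndarray:
        return np.concatenate([c.period_starts for c in self.calendars])

    @property
    def period_years(self) -> np.ndarray:
        return np.repeat(self.years, 46)

    @property
    def missing_mask(self) -> np.ndarray:
        """True where any meteorological driver or LAI is missing."""
        return (
            np.isnan(self.lai)
            | np.isnan(self.rn)
            | np.isnan(self.ta)
            | np.isnan(self.rh)
        )


# --- NetCDF read/write -------------------------------------------------------

def _forcing_dataset(forcing: ForcingFields, name: str, arr: np.ndarray) -> xr.Dataset:
    ds = xr.Dataset(
        {name: (("time", "lat", "lon"), arr.astype(np.float32))},
        coords={
            "time": np.arange(forcing.n_time),
            "lat": forcing.grid.lats,
            "lon": forcing.grid.lons,
            "period_start_doy": ("time", forcing.period_starts),
            "period_year": ("time", forcing.period_years),
        },
    )
    ds[name].encoding["_FillValue"] = np.float32(FILL_VALUE)
    ds["time"].encoding["dtype"] = np.int32
    ds["period_start_doy"].encoding["dtype"] = np.int32
    ds["period_year"].encoding["dtype"] = np.int32
    ds.attrs["years"] = np.asarray(forcing.years, dtype=np.int32)
    return ds


def write_forcing(forcing: ForcingFields, outdir) -> dict[str, Path]:
    """Write one NetCDF file per forcing variable plus the land-cover raster.

    Returns a mapping variable name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in FORCING_VARS:
        arr = getattr(forcing, name)
        path = outdir / f"forcing_{name}.nc"
        _forcing_dataset(forcing, name, arr).to_netcdf(path, engine="scipy")
        paths[name] = path
    lc = xr.Dataset(
        {"landcover": (("lat", "lon"), forcing.landcover.astype(np.float32))},
        coords={"lat": forcing.grid.lats, "lon": forcing.grid.lons},
    )
    lc["landcover"].encoding["_FillValue"] = np.float32(FILL_VALUE)
    lc.attrs["classes"] = " ".join(f"{k}={v}" for k, v in LANDCOVER_CODES.items())
    path = outdir / "landcover.nc"
    lc.to_netcdf(path, engine="scipy")
    paths["landcover"] = path
    return paths


def _open_var(path, name_hint=None):
    ds = xr.open_dataset(path, engine="scipy")
    try:
        if "lat" not in ds.coords or "lon" not in ds.coords:
            raise ForcingFormatError(f"{path}: missing lat/lon coordinate variables")
        data_vars = [v for v in ds.data_vars if {"lat", "lon"} <= set(ds[v].dims)]
        if not data_vars:
            raise ForcingFormatError(f"{path}: no gridded data variable found")
        name = name_hint if name_hint in data_vars else data_vars[0]
        da = ds[name].load()
        attrs = dict(ds.attrs)
        extra = {
            c: ds[c].values.copy()
            for c in ("period_start_doy", "period_year")
            if c in ds.coords
        }
    finally:
        ds.close()
    return da, attrs, extra


def read_forcing(paths: dict, grid: GridSpec | None = None) -> ForcingFields:
    """Read per-variable NetCDF files onto the target grid.

    ``paths`` maps variable names (lai, rn, ta, rh, landcover, optionally g)
    to file paths.  Variables on a different grid are regridded
    (area-weighted for continuous fields, majority for land cover); relative
    humidity in percent is converted to a fraction; fill values become NaN.
    """
    missing = [k for k in ("lai", "rn", "ta", "rh", "landcover") if k not in paths]
    if missing:
        raise ForcingFormatError(f"missing forcing paths for: {missing}")

    fields: dict[str, np.ndarray] = {}
    years: tuple[int, ...] | None = None
    for name, path in paths.items():
        da, attrs, extra = _open_var(path, name)
        lats = da["lat"].values
        src_grid = GridSpec.from_coords(lats, da["lon"].values)
        if grid is None:
            grid = src_grid
        if grid.lat_min >= src_grid.lat_max or grid.lat_max <= src_grid.lat_min or \
           grid.lon_min >= src_grid.lon_max or grid.lon_max <= src_grid.lon_min:
            raise ValueError(f"{path}: spatial domain does not overlap target grid")
        arr = da.values.astype(float)
        # normalize latitude to descending (N -> S)
        lat_axis = da.dims.index("lat")
        if lats.size > 1 and lats[0] < lats[-1]:
            arr = np.flip(arr, axis=lat_axis)
        if name == "rh":
            valid = arr[np.isfinite(arr)]
            if valid.size and valid.max() > 1.5:  # percent, not fraction
                arr = arr / 100.0
        if name == "landcover":
            arr2 = arr if arr.ndim == 2 else arr[0]
            out = regrid(arr2, src_grid, grid, mode="categorical")
            fields[name] = np.where(np.isnan(out), NONVEG, out).astype(int)
        else:
            out = np.stack(
                [regrid(arr[i], src_grid, grid, mode="continuous")
                 for i in range(arr.shape[0])]
            ) if arr.ndim == 3 else regrid(arr, src_grid, grid, mode="continuous")[None]
            fields[name] = out
            if years is None:
                if "years" in attrs:
                    ylist = attrs["years"]
                    years = tuple(int(y) for y in np.atleast_1d(ylist))
                elif "period_year" in extra:
                    years = tuple(np.unique(extra["period_year"]).astype(int))
    if years is None:
        n_years = max(1, fields["lai"].shape[0] // 46)
        years = tuple(range(2001, 2001 + n_years))
    return ForcingFields(
        grid=grid,
        years=years,
        lai=fields["lai"],
        rn=fields["rn"],
        ta=fields["ta"],
        rh=fields["rh"],
        g=fields.get("g"),
        landcover=fields["landcover"],
    )


# --- regridding --------------------------------------------------------------

def _overlap_weights(src_edges: np.ndarray, dst_edges: np.ndarray) -> np.ndarray:
    """Interval-overlap matrix W[i, j] = |dst_i intersect src_j| (degrees)."""
    lo = np.maximum(dst_edges[:-1, None], src_edges[None, :-1])
    hi = np.minimum(dst_edges[1:, None], src_edges[None, 1:])
    return np.maximum(hi - lo, 0.0)


def regrid(field, src: GridSpec, dst: GridSpec, mode: str = "continuous"):
    """Conservative (area-overlap) regridding between regular lat/lon grids.

    Continuous fields take the area-weighted mean of overlapping source
    cells (missing source cells are excluded and weights renormalized);
    categorical fields take the class with the largest overlapping area
    (majority vote when coarsening, nearest cell when refining).  Cells with
    no valid source coverage are NaN.
    """
    field = np.asarray(field)
    if field.shape != (src.n_lat, src.n_lon):
        raise ValueError(f"field shape {field.shape} != src grid {(src.n_lat, src.n_lon)}")
    if mode not in ("continuous", "categorical"):
        raise ValueError("mode must be 'continuous' or 'categorical'")
    if mode == "continuous" and field.dtype.kind in "iu":
        raise TypeError(
            "integer-coded (categorical) field passed with mode='continuous'; "
            "use mode='categorical'"
        )
    same_grid = (
        src.n_lat == dst.n_lat
        and src.n_lon == dst.n_lon
        and np.allclose(src.lats, dst.lats)
        and np.allclose(src.lons, dst.lons)
    )
    if same_grid:  # identity; also keeps missing cells missing bit-exactly
        if mode == "continuous":
            return field.astype(float).copy()
        return field.astype(float).copy()
    w_lat = _overlap_weights(src.lat_edges, dst.lat_edges)  # (dst, src), ascending
    w_lon = _overlap_weights(src.lon_edges, dst.lon_edges)
    # drop numerically spurious slivers from edge rounding
    tiny = 1e-6 * min(src.cell_size, dst.cell_size)
    w_lat[w_lat < tiny] = 0.0
    w_lon[w_lon < tiny] = 0.0
    # Latitude arrays are stored descending; flip the weight columns/rows.
    w_lat = w_lat[::-1, :][:, ::-1]
    if mode == "continuous":
        f = field.astype(float)
        valid = np.isfinite(f).astype(float)
        num = w_lat @ np.where(np.isfinite(f), f, 0.0) @ w_lon.T
        den = w_lat @ valid @ w_lon.T
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / den, np.nan)
        return out
    # categorical: accumulate overlap mass per class, argmax (ties -> lowest code)
    f = field.astype(float)
    classes = np.unique(f[np.isfinite(f)]).astype(int)
    if classes.size == 0:
        return np.full((dst.n_lat, dst.n_lon), np.nan)
    mass = np.empty((classes.size, dst.n_lat, dst.n_lon))
    for ci, c in enumerate(classes):
        mass[ci] = w_lat @ (f == c).astype(float) @ w_lon.T
    total = mass.sum(axis=0)
    winner = classes[np.argmax(mass, axis=0)].astype(float)
    return np.where(total > 0, winner, np.nan)


# --- temporal compositing ----------------------------------------------------

def composite_to_8day(daily: np.ndarray, calendar: CompositingCalendar) -> np.ndarray:
    """Average a daily series (day 1 .. 365/366 first axis) into 46 periods.

    Each period value is the mean of available (non-NaN) daily values in the
    period; an all-missing period is NaN.
    """
    daily = np.asarray(daily, float)
    if daily.shape[0] != calendar.days_in_year:
        raise CalendarError(
            f"daily series has {daily.shape[0]} days; calendar year "
            f"{calendar.year} has {calendar.days_in_year}"
        )
    out = np.empty((46,) + daily.shape[1:])
    starts = calendar.period_starts
    lengths = calendar.period_lengths
    for p in range(46):
        chunk = daily[starts[p] - 1 : starts[p] - 1 + lengths[p]]
        valid = np.isfinite(chunk)
        with np.errstate(invalid="ignore"):
            s = np.where(valid, chunk, 0.0).sum(axis=0)
            n = valid.sum(axis=0)
            out[p] = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return out
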