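"""Gridded simulation: apply biome-calibrated parameters across the forcing
grid, aggregate to 8-day and annual products, and write the NetCDF dataset.

Output layout mirrors the published product: per-variable annual files
(``Annual_T.nc``, ``Annual_ET.nc``, ``Annual_T_ET.nc``, one layer per year)
and per-year 8-day files (``Daily_T_TTTT.nc`` etc., 46 layers each, with
the start and end day-of-year of every averaging period stored as
coordinates).  Fill value is -9999; non-vegetated pixels and near-zero-ET
ratios are filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import xarray as xr

from .forcing_io import (
    ForcingFields,
    GridSpec,
    LANDCOVER_CODES,
    LANDCOVER_NAMES,
    VEGETATED_CLASSES,
)
from .ptjpl import (
    BiomeParams,
    FILL_VALUE,
    TET_EPSILON,
    estimate_fapar_max,
    estimate_topt,
    ptjpl_fluxes,
    wm2_to_mm,
)

__all__ = [
    "ParamLUT",
    "FluxCube",
    "AnnualProduct",
    "build_lut",
    "run_grid",
    "tet_8day",
    "aggregate_annual",
    "write_dataset",
    "read_product",
]


@dataclass
class ParamLUT:
    """Biome parameter table plus the per-pixel derived parameter grids."""

    params: dict[str, BiomeParams]
    topt: np.ndarray        # (n_lat, n_lon) optimum temperature, deg C
    fapar_max: np.ndarray   # (n_lat, n_lon)


@dataclass
class FluxCube:
    """Per-period flux grids in mm per period; NaN = missing/fill."""

    es: np.ndarray
    ei: np.ndarray
    t: np.ndarray
    et: np.ndarray
    years: tuple[int, ...]
    grid: GridSpec
    period_lengths: np.ndarray
    period_starts: np.ndarray


@dataclass
class AnnualProduct:
    """Annual T, ET (mm a^-1) and T/ET grids plus a gap diagnostic."""

    t: np.ndarray            # (n_years, n_lat, n_lon)
    et: np.ndarray
    tet: np.ndarray
    gap_fraction: np.ndarray
    years: tuple[int, ...]
    grid: GridSpec


def build_lut(forcing: ForcingFields, params: dict[str, BiomeParams]) -> ParamLUT:
    """Derive the per-pixel T_opt and f_APARmax grids for a parameter table.

    Pixels whose biome entry carries a fixed ``t_opt`` use it directly;
    entries with ``t_opt=None`` use the per-pixel rule (air temperature at
    the record maximum of LAI * Ta * f_APAR).
    """
    lc = forcing.landcover
    topt = np.full(lc.shape, np.nan)
    fam = np.full(lc.shape, np.nan)
    for biome in VEGETATED_CLASSES:
        if biome not in params:
            continue
        mask = lc == LANDCOVER_CODES[biome]
        if not mask.any():
            continue
        p = params[biome]
        lai = forcing.lai[:, mask]
        f_apar = p.b1 * (1.0 - np.exp(-p.k1 * lai))
        fam[mask] = estimate_fapar_max(f_apar, axis=0)
        if p.t_opt is None:
            topt[mask] = estimate_topt(forcing.ta[:, mask], lai, f_apar, axis=0)
        else:
            topt[mask] = p.t_opt
    return ParamLUT(params=params, topt=topt, fapar_max=fam)


def run_grid(forcing: ForcingFields, lut: ParamLUT) -> FluxCube:
    """Simulate per-period fluxes (mm per period) over the whole grid.

    Each vegetated cell is evaluated with its biome's parameters and its
    per-pixel T_opt / f_APARmax; non-vegetated cells and cells with missing
    forcing are NaN.  Cells are independent (no cross-cell coupling).
    """
    lc = forcing.landcover
    present = {int(c) for c in np.unique(lc)}
    known = set(LANDCOVER_CODES.values())
    unknown = present - known
    if unknown:
        raise ValueError(f"unknown land-cover codes in forcing: {sorted(unknown)}")
    needed = {LANDCOVER_NAMES[c] for c in present} & set(VEGETATED_CLASSES)
    absent = needed - set(lut.params)
    if absent:
        raise ValueError(f"land-cover classes missing from the LUT: {sorted(absent)}")

    shape = forcing.lai.shape
    es = np.full(shape, np.nan)
    ei = np.full(shape, np.nan)
    t = np.full(shape, np.nan)
    et = np.full(shape, np.nan)
    plen = forcing.period_lengths[:, None]
    for biome in VEGETATED_CLASSES:
        mask = lc == LANDCOVER_CODES[biome]
        if not mask.any():
            continue
        p = lut.params[biome]
        fx = ptjpl_fluxes(
            forcing.ta[:, mask],
            forcing.rh[:, mask],
            forcing.lai[:, mask],
            forcing.rn[:, mask],
            p,
            lut.fapar_max[mask],
            g=forcing.g[:, mask],
            t_opt=lut.topt[mask],
        )
        es[:, mask] = wm2_to_mm(fx.es, plen)
        ei[:, mask] = wm2_to_mm(fx.ei, plen)
        t[:, mask] = wm2_to_mm(fx.t, plen)
        et[:, mask] = wm2_to_mm(fx.et, plen)
    return FluxCube(
        es=es,
        ei=ei,
        t=t,
        et=et,
        years=forcing.years,
        grid=forcing.grid,
        period_lengths=forcing.period_lengths,
        period_starts=forcing.period_starts,
    )


def tet_8day(t: np.ndarray, et: np.ndarray, epsilon: float = TET_EPSILON) -> np.ndarray:
    """Per-period T/ET ratio; NaN (fill) where ET <= epsilon or missing."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(et > epsilon, t / et, np.nan)


def aggregate_annual(cube: FluxCube, epsilon: float = TET_EPSILON) -> AnnualProduct:
    """Annual sums of T and ET and their ratio.

    All periods of a year contribute; gap periods (missing flux) contribute
    zero, and a gap-fraction diagnostic layer records how much of each
    pixel-year was gap-filled that way.  Pixels with no valid period at all
    (e.g. non-vegetated) stay missing.  Annual T/ET is the ratio of annual
    sums (cumulative T over cumulative ET), not the mean of period ratios.
    """
    n_years = len(cube.years)
    shape = (n_years, 46) + cube.t.shape[1:]
    t_y = cube.t.reshape(shape)
    et_y = cube.et.reshape(shape)
    valid = np.isfinite(et_y)
    any_valid = valid.any(axis=1)
    t_ann = np.where(any_valid, np.nansum(t_y, axis=1), np.nan)
    et_ann = np.where(any_valid, np.nansum(et_y, axis=1), np.nan)
    gap_fraction = 1.0 - valid.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tet = np.where(et_ann > epsilon, t_ann / et_ann, np.nan)
    return AnnualProduct(
        t=t_ann,
        et=et_ann,
        tet=tet,
        gap_fraction=gap_fraction,
        years=cube.years,
        grid=cube.grid,
    )


# --- dataset writer ----------------------------------------------------------

_ANNUAL_TEMPLATE = "Annual_{var}.nc"
_DAILY_TEMPLATE = "Daily_{var}_{year}.nc"


def _encode(da: xr.DataArray) -> xr.DataArray:
    da.encoding["_FillValue"] = np.float32(FILL_VALUE)
    da.encoding["dtype"] = np.float32
    return da


def write_dataset(
    annual: AnnualProduct,
    cube: FluxCube | None,
    outdir,
    overwrite: bool = False,
) -> list[dict]:
    """Write the annual (and optionally 8-day) product files.

    Returns a manifest of ``{"path", "variable", "n_layers"}`` entries.
    Refuses to clobber existing files unless ``overwrite`` is set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    grid = annual.grid
    coords = {"lat": grid.lats, "lon": grid.lons}

    def _write(ds: xr.Dataset, path: Path, variable: str, n_layers: int):
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists (pass overwrite=True to replace)")
        ds.to_netcdf(path, engine="scipy")
        manifest.append({"path": str(path), "variable": variable, "n_layers": n_layers})

    annual_fields = {"T": annual.t, "ET": annual.et, "T_ET": annual.tet}
    for var, arr in annual_fields.items():
        ds = xr.Dataset(
            {var: _encode(xr.DataArray(
                arr, dims=("year", "lat", "lon"),
                coords={"year": list(annual.years), **coords},
            ))}
        )
        ds.attrs["fill_value"] = FILL_VALUE
        _write(ds, outdir / _ANNUAL_TEMPLATE.format(var=var), var, len(annual.years))

    if cube is not None:
        tet = tet_8day(cube.t, cube.et)
        daily_fields = {"T": cube.t, "ET": cube.et, "T_ET": tet}
        for yi, year in enumerate(cube.years):
            sl = slice(46 * yi, 46 * (yi + 1))
            starts = cube.period_starts[sl]
            ends = starts + cube.period_lengths[sl] - 1
            for var, arr in daily_fields.items():
                ds = xr.Dataset(
                    {var: _encode(xr.DataArray(
                        arr[sl], dims=("time", "lat", "lon"),
                        coords={
                            "time": np.arange(46),
                            "period_start_doy": ("time", starts),
                            "period_end_doy": ("time", ends),
                            **coords,
                        },
                    ))}
                )
                ds.attrs["year"] = np.int32(year)
                ds.attrs["fill_value"] = FILL_VALUE
                _write(
                    ds, outdir / _DAILY_TEMPLATE.format(var=var, year=year), var, 46
                )
    return manifest


def read_product(path, variable: str | None = None) -> xr.DataArray:
    """Read a product file back (fill values decoded to NaN)."""
    ds = xr.open_dataset(path, engine="scipy")
    try:
        name = variable or list(ds.data_vars)[0]
        return ds[name].load()
    finally:
        ds.close()
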