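"""Synthetic forcing and observation generator.

Emulates the statistical structure of the real model inputs — gridded LAI,
net radiation, air temperature and relative humidity on a 0.05 degree
8-day grid with a static land-cover raster — and of the site observation
tables (annual transpiration and annual evapotranspiration per site-year,
biome-tagged), so that sensitivity analysis, calibration, gridded
simulation and validation are all testable offline.

What it emulates: seasonal sinusoidal climate with a weak meridional
temperature gradient, net radiation coupled to the temperature season,
relative humidity anticorrelated with the VPD season, biome-specific LAI
phenology with an optional year-on-year greening trend, random forcing
gaps, and multiplicative lognormal observation noise (flux magnitudes are
positive and errors scale with magnitude).  What it does not emulate:
sensor artifacts, orbital drift, spatial error correlation, sub-pixel
site/footprint mismatch, or energy-balance closure errors.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .demc import ObservationSet, SiteDrivers
from .forcing_io import (
    ForcingFields,
    GridSpec,
    LANDCOVER_CODES,
    VEGETATED_CLASSES,
)
from .ptjpl import BiomeParams, default_biome_params

__all__ = [
    "ClimateCycle",
    "SynthConfig",
    "trend_config",
    "generate_forcing",
    "generate_observations",
    "default_true_params",
    "write_synthetic_dataset",
]


@dataclass(frozen=True)
class ClimateCycle:
    """Seasonal sinusoid parameters for one biome's local climate.

    Each driver follows mean + amplitude * cos(2 pi (doy - peak_doy)/365);
    relative humidity uses a negative amplitude sign internally so it is
    lowest when the VPD season peaks.
    """

    ta_mean: float = 12.0     # deg C
    ta_amp: float = 12.0
    rn_mean: float = 110.0    # W m^-2
    rn_amp: float = 75.0
    rh_mean: float = 0.65     # fraction
    rh_amp: float = 0.12
    lai_max: float = 3.5      # m2 m-2
    lai_min: float = 0.2
    peak_doy: float = 200.0


_DEFAULT_CLIMATE = {
    "forest": ClimateCycle(ta_mean=12.0, lai_max=4.5, lai_min=0.5, rh_mean=0.70),
    "shrub": ClimateCycle(ta_mean=10.0, lai_max=2.5, lai_min=0.2, rh_mean=0.60),
    "grass": ClimateCycle(ta_mean=8.0, lai_max=2.0, lai_min=0.1, rh_mean=0.55),
    "crop": ClimateCycle(ta_mean=14.0, lai_max=3.5, lai_min=0.1, rh_mean=0.65),
    "nonveg": ClimateCycle(ta_mean=12.0, lai_max=0.0, lai_min=0.0, rh_mean=0.40),
}

#: Fixed optimum temperatures used for the synthetic "truth" (the per-pixel
#: argmax rule needs a known number to score parameter recovery against).
_TRUE_TOPT = {"forest": 20.0, "shrub": 22.0, "grass": 18.0, "crop": 24.0}


def default_true_params() -> dict[str, BiomeParams]:
    """The packaged biome parameters with concrete t_opt values, used as
    the data-generating truth."""
    lut = default_biome_params()
    return {
        b: p.replace(t_opt=_TRUE_TOPT[b]) for b, p in lut.items() if b in _TRUE_TOPT
    }


@dataclass
class SynthConfig:
    """Configuration of the synthetic world.

    Defaults describe a desk-scale experiment: a 10 x 10 cell 0.05-degree
    grid split into five biome bands, three years of 8-day forcing, 5%
    multiplicative observation noise, 2% forcing gaps, and a 0.5% per-year
    multiplicative LAI greening trend (switched off by setting
    ``lai_trend=0``).
    """

    grid: GridSpec = field(
        default_factory=lambda: GridSpec(30.0, 30.5, 100.0, 100.5, 0.05)
    )
    years: tuple[int, ...] = (2001, 2002, 2003)
    true_params: dict[str, BiomeParams] = field(default_factory=default_true_params)
    climate: dict[str, ClimateCycle] = field(
        default_factory=lambda: dict(_DEFAULT_CLIMATE)
    )
    noise_cv: float = 0.05
    gap_prob: float = 0.02
    lai_trend: float = 0.005
    n_sites_et: int = 10
    n_sites_t: int = 6
    max_years_per_site: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gap_prob <= 0.5:
            raise ValueError("gap_prob must be in [0, 0.5]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def trend_config(seed: int = 0, n_years: int = 35) -> SynthConfig:
    """A 6 x 6 grid, multi-decade configuration for trend experiments."""
    return SynthConfig(
        grid=GridSpec(30.0, 30.3, 100.0, 100.3, 0.05),
        years=tuple(range(1981, 1981 + n_years)),
        seed=seed,
    )


def _biome_bands(grid: GridSpec) -> np.ndarray:
    """Split grid rows into five horizontal bands, one per class."""
    lc = np.empty((grid.n_lat, grid.n_lon), dtype=int)
    order = ("forest", "shrub", "grass", "crop", "nonveg")
    bands = np.array_split(np.arange(grid.n_lat), 5)
    for cls, rows in zip(order, bands):
        lc[rows, :] = LANDCOVER_CODES[cls]
    return lc


def generate_forcing(config: SynthConfig) -> ForcingFields:
    """Generate the gridded 8-day forcing for the configured world.

    Deterministic for a given config (all randomness from ``seed``).
    """
    grid = config.grid
    years = config.years
    lc = _biome_bands(grid)
    n_lat, n_lon = grid.n_lat, grid.n_lon
    n_time = 46 * len(years)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    doy_mid = []
    year_index = []
    for k, y in enumerate(years):
        from .forcing_io import CompositingCalendar

        cal = CompositingCalendar(y)
        doy_mid.append(cal.period_starts + (cal.period_lengths - 1) / 2.0)
        year_index.extend([k] * 46)
    doy_mid = np.concatenate(doy_mid)
    year_index = np.asarray(year_index)

    ta = np.empty((n_time, n_lat, n_lon))
    rn = np.empty_like(ta)
    rh = np.empty_like(ta)
    lai = np.empty_like(ta)
    # weak meridional gradient: cooler toward the northern rows
    lat_gradient = -0.3 * np.arange(n_lat)[::-1]
    for cls, code in LANDCOVER_CODES.items():
        mask = lc == code
        if not mask.any():
            continue
        c = config.climate[cls]
        s = np.cos(2.0 * np.pi * (doy_mid - c.peak_doy) / 365.0)[:, None]
        ta_f = c.ta_mean + c.ta_amp * s + lat_gradient[None, :, None].repeat(n_lon, 2)[:, mask]
        rn_f = c.rn_mean + c.rn_amp * s
        rh_f = c.rh_mean + c.rh_amp * (-s)  # driest when the VPD season peaks
        phen = ((1.0 + s) / 2.0) ** 1.5
        growth = (1.0 + config.lai_trend) ** year_index[:, None]
        lai_f = (c.lai_min + (c.lai_max - c.lai_min) * phen) * growth
        npix = int(mask.sum())
        ta[:, mask] = ta_f + rng.normal(0.0, 0.4, (n_time, npix))
        rn[:, mask] = np.maximum(rn_f + rng.normal(0.0, 4.0, (n_time, npix)), 5.0)
        rh[:, mask] = np.clip(rh_f + rng.normal(0.0, 0.02, (n_time, npix)), 0.2, 1.0)
        lai[:, mask] = np.maximum(
            lai_f * (1.0 + rng.normal(0.0, 0.03, (n_time, npix))), 0.0
        )
    if config.gap_prob > 0:
        gaps = rng.random((n_time, n_lat, n_lon)) < config.gap_prob
        for arr in (ta, rn, rh, lai):
            arr[gaps] = np.nan
    return ForcingFields(
        grid=grid, years=years, lai=lai, rn=rn, ta=ta, rh=rh, landcover=lc
    )


def generate_observations(
    config: SynthConfig, forcing: ForcingFields
) -> tuple[ObservationSet, dict]:
    """Sample site pixels, run the model truth, add observation noise.

    Per vegetated biome, up to ``n_sites_et`` pixel-center sites report
    annual ET for 1..``max_years_per_site`` years; the first
    ``n_sites_t`` of them also report annual T (transpiration observations
    are scarcer in practice — sap flow covers fewer sites than eddy
    covariance).  Noise is multiplicative lognormal with mean one and
    coefficient of variation ``noise_cv``.

    Returns the observation set and a truth record (true parameters plus
    the noise-free value for every observation row).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    grid = forcing.grid
    lc = forcing.landcover
    n_years = len(forcing.years)
    sigma = np.sqrt(np.log(1.0 + config.noise_cv**2))

    rows = []
    truth_records = []
    for biome in VEGETATED_CLASSES:
        mask = lc == LANDCOVER_CODES[biome]
        cells = np.argwhere(mask)
        if cells.size == 0:
            raise ValueError(f"no pixels for requested biome {biome!r}")
        n_sites = min(config.n_sites_et, len(cells))
        chosen = cells[rng.choice(len(cells), size=n_sites, replace=False)]
        sites = pd.DataFrame(
            {
                "site_id": [f"{biome}_{k:02d}" for k in range(n_sites)],
                "lat": grid.lats[chosen[:, 0]],
                "lon": grid.lons[chosen[:, 1]],
                "biome": biome,
            }
        )
        drivers = SiteDrivers.from_forcing(forcing, sites)
        annual_t, annual_et = drivers.annual_fluxes(config.true_params[biome])
        for k, site in sites.iterrows():
            n_rec = int(rng.integers(1, min(config.max_years_per_site, n_years) + 1))
            year_idx = np.sort(rng.choice(n_years, size=n_rec, replace=False))
            for yi in year_idx:
                year = forcing.years[yi]
                variables = ["ET"] if k >= config.n_sites_t else ["ET", "T"]
                for var in variables:
                    truth = float(annual_et[yi, k] if var == "ET" else annual_t[yi, k])
                    factor = float(np.exp(rng.normal(-0.5 * sigma**2, sigma))) \
                        if sigma > 0 else 1.0
                    rows.append(
                        {
                            "site_id": site["site_id"],
                            "lat": site["lat"],
                            "lon": site["lon"],
                            "biome": biome,
                            "year": int(year),
                            "variable": var,
                            "value_mm_per_year": truth * factor,
                        }
                    )
                    truth_records.append(
                        {
                            "site_id": site["site_id"],
                            "biome": biome,
                            "year": int(year),
                            "variable": var,
                            "truth_mm_per_year": truth,
                        }
                    )
    df = pd.DataFrame(rows)
    obs = ObservationSet(
        {str(v): g.reset_index(drop=True) for v, g in df.groupby("variable")}
    )
    truth = {
        "params": {
            b: dataclasses.asdict(p) for b, p in config.true_params.items()
        },
        "noise_cv": config.noise_cv,
        "seed": config.seed,
        "records": truth_records,
    }
    return obs, truth


def write_synthetic_dataset(config: SynthConfig, outdir) -> dict:
    """Generate and write forcing NetCDFs, observation CSVs and truth JSON.

    Returns a manifest of written paths.
    """
    from .forcing_io import write_forcing

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    forcing = generate_forcing(config)
    paths = write_forcing(forcing, outdir)
    obs, truth = generate_observations(config, forcing)
    obs_t = outdir / "obs_T.csv"
    obs_et = outdir / "obs_ET.csv"
    for var, path in (("T", obs_t), ("ET", obs_et)):
        if var in obs.datasets:
            obs.datasets[var].assign(variable=var).to_csv(path, index=False)
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    manifest = {k: str(v) for k, v in paths.items()}
    manifest.update({"obs_T": str(obs_t), "obs_ET": str(obs_et), "truth": str(truth_path)})
    return manifest
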