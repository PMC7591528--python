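"""PT-JPL evapotranspiration partitioning model core.

The Priestley-Taylor Jet Propulsion Laboratory (PT-JPL) model partitions
total evapotranspiration into soil evaporation (ES), canopy interception
evaporation (EI) and plant transpiration (T):

    ET = ES + EI + T
    ES = (f_wet + f_sm (1 - f_wet)) * alpha * Delta/(Delta+gamma) * (R_ns - G)
    EI = f_wet * alpha * Delta/(Delta+gamma) * R_nc
    T  = (1 - f_wet) * f_g * f_t * f_m * alpha * Delta/(Delta+gamma) * R_nc

Net radiation R_n is split between soil and canopy by Beer-Lambert
extinction, R_ns = R_n * exp(-k_Rn * LAI), R_nc = R_n - R_ns.  The
multiplicative eco-physiological constraints (all dimensionless, in [0, 1])
scale the Priestley-Taylor potential rate down to actual fluxes:

    f_wet  = RH^4                        relative surface wetness
    f_g    = f_APAR / f_IPAR             green canopy fraction
    f_t    = exp(-((Ta - T_opt)/T_opt)^2)  plant temperature constraint
    f_sm   = RH^(VPD/beta)               soil moisture constraint
    f_m    = f_APAR / f_APARmax          plant moisture constraint
    f_APAR = b1 (1 - exp(-k1 LAI)),  f_IPAR = b2 (1 - exp(-k2 LAI))

RH is a fraction in [0, 1]; VPD in kPa; Ta in degrees C; fluxes in W m^-2
(convert to mm with the latent heat of vaporization, see ``wm2_to_mm``).

All functions are vectorized over numpy arrays and propagate NaN as
"missing": domain checks apply to finite entries only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ALPHA_PT",
    "GAMMA_PSY",
    "LAMBDA_MJ",
    "FILL_VALUE",
    "TET_EPSILON",
    "BiomeParams",
    "ConstraintSet",
    "FluxFields",
    "saturation_vapor_pressure",
    "saturation_slope",
    "vapor_pressure_deficit",
    "constraints",
    "partition_radiation",
    "ptjpl_fluxes",
    "estimate_topt",
    "estimate_fapar_max",
    "priestley_taylor_potential",
    "wm2_to_mm",
    "default_biome_params",
    "load_biome_params",
    "save_biome_params",
]

#: Priestley-Taylor coefficient for a wet surface (dimensionless).
ALPHA_PT = 1.26
#: Psychrometric constant (kPa per degree C).
GAMMA_PSY = 0.066
#: Latent heat of vaporization (MJ per kg of water).
LAMBDA_MJ = 2.45
#: Fill value used throughout the gridded products.
FILL_VALUE = -9999.0
#: Below this ET (mm per period) the ratio T/ET is reported as missing.
TET_EPSILON = 1e-6

#: Seconds in a day times 1e-6: converts W m^-2 to MJ m^-2 day^-1.
_WM2_TO_MJ_DAY = 0.0864


@dataclass(frozen=True)
class BiomeParams:
    """The seven tunable PT-JPL parameters for one biome.

    ``b1``/``b2`` are the asymptotes of the absorbed/intercepted PAR
    fractions; ``k1``/``k2`` their canopy extinction coefficients;
    ``t_opt`` the optimum plant growth temperature (deg C, ``None`` means
    "derive per pixel from the forcing record" via :func:`estimate_topt`);
    ``beta`` the VPD sensitivity of the soil moisture constraint (kPa);
    ``k_rn`` the net-radiation extinction coefficient.  ``alpha`` and
    ``gamma`` are physical constants, fixed unless explicitly overridden.
    """

    b1: float = 1.0
    b2: float = 1.0
    k1: float = 0.6
    k2: float = 0.6
    t_opt: float | None = None
    beta: float = 1.0
    k_rn: float = 0.6
    alpha: float = ALPHA_PT
    gamma: float = GAMMA_PSY

    def __post_init__(self) -> None:
        for name in ("b1", "b2"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.5:
                raise ValueError(f"{name}={v} outside (0, 1.5]")
        for name in ("k1", "k2", "beta", "k_rn"):
            v = getattr(self, name)
            if not v > 0.0:
                raise ValueError(f"{name}={v} must be positive")
        if self.t_opt is not None and self.t_opt == 0.0:
            raise ValueError("t_opt must be nonzero (divides the f_t exponent)")

    def replace(self, **changes) -> "BiomeParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ConstraintSet:
    """Evaluated constraint functions plus the thermodynamic quantities."""

    f_wet: np.ndarray
    f_g: np.ndarray
    f_t: np.ndarray
    f_m: np.ndarray
    f_sm: np.ndarray
    f_apar: np.ndarray
    f_ipar: np.ndarray
    delta: np.ndarray
    vpd: np.ndarray
    f_apar_max: np.ndarray


@dataclass(frozen=True)
class FluxFields:
    """PT-JPL flux components; ``et == es + ei + t`` exactly."""

    es: np.ndarray
    ei: np.ndarray
    t: np.ndarray
    et: np.ndarray

    def tet(self, epsilon: float = TET_EPSILON) -> np.ndarray:
        """T/ET ratio, NaN where ET <= epsilon."""
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(self.et > epsilon, self.t / self.et, np.nan)
        return out


def _check_domain(x, lo, hi, name):
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    if np.any((x[finite] < lo) | (x[finite] > hi)):
        raise ValueError(f"{name} outside [{lo}, {hi}]")
    return x


def saturation_vapor_pressure(ta):
    """Saturation vapor pressure e_s(Ta) in kPa (FAO-56 Tetens form)."""
    ta = np.asarray(ta, dtype=float)
    return 0.6108 * np.exp(17.27 * ta / (ta + 237.3))


def saturation_slope(ta):
    """Slope Delta of the saturation vapor pressure curve (kPa / deg C).

    FAO-56 closed form: Delta = 4098 e_s(Ta) / (Ta + 237.3)^2.  Strictly
    increasing over the valid range Ta in [-40, 60] deg C.
    """
    ta = _check_domain(ta, -40.0, 60.0, "ta")
    return 4098.0 * saturation_vapor_pressure(ta) / (ta + 237.3) ** 2


def vapor_pressure_deficit(ta, rh):
    """VPD = e_s(Ta) * (1 - RH) in kPa, RH a fraction in [0, 1]."""
    rh = _check_domain(rh, 0.0, 1.0, "rh")
    return saturation_vapor_pressure(ta) * (1.0 - rh)


def constraints(ta, rh, lai, params: BiomeParams, f_apar_max, t_opt=None) -> ConstraintSet:
    """Evaluate all PT-JPL constraint functions at the given forcing.

    Parameters
    ----------
    ta, rh, lai : array-like
        Air temperature (deg C), relative humidity (fraction), leaf area
        index (m2 m-2); broadcast against each other.
    params : BiomeParams
        Must carry a concrete (nonzero) ``t_opt`` unless ``t_opt`` is given.
    f_apar_max : array-like
        Per-pixel maximum absorbed-PAR fraction (see
        :func:`estimate_fapar_max`); must be > 0.
    t_opt : array-like, optional
        Per-pixel optimum temperature overriding ``params.t_opt`` (deg C,
        nonzero), e.g. from :func:`estimate_topt`.

    Returns
    -------
    ConstraintSet with every constraint clipped into [0, 1].
    """
    if t_opt is None:
        t_opt = params.t_opt
    if t_opt is None:
        raise ValueError(
            "t_opt unresolved: set params.t_opt or pass a per-pixel t_opt "
            "(e.g. from estimate_topt)"
        )
    t_opt = np.asarray(t_opt, dtype=float)
    if np.any(t_opt[np.isfinite(t_opt)] == 0.0):
        raise ValueError("t_opt must be nonzero (divides the f_t exponent)")
    rh = _check_domain(rh, 0.0, 1.0, "rh")
    ta = np.asarray(ta, dtype=float)
    lai = np.asarray(lai, dtype=float)
    fam = np.asarray(f_apar_max, dtype=float)
    finite_lai = np.isfinite(lai)
    if np.any(lai[finite_lai] < 0):
        raise ValueError("lai must be >= 0")
    if np.any(fam[np.isfinite(fam)] <= 0):
        raise ValueError("f_apar_max must be > 0")

    f_wet = rh**4
    f_apar = params.b1 * (1.0 - np.exp(-params.k1 * lai))
    f_ipar = params.b2 * (1.0 - np.exp(-params.k2 * lai))
    with np.errstate(invalid="ignore", divide="ignore"):
        f_g = np.where(f_ipar > 0, np.clip(f_apar / f_ipar, 0.0, 1.0), 0.0)
        f_g = np.where(np.isnan(f_ipar), np.nan, f_g)
    delta = saturation_slope(ta)
    vpd = saturation_vapor_pressure(ta) * (1.0 - rh)
    f_t = np.exp(-(((ta - t_opt) / t_opt) ** 2))
    # RH^(VPD/beta): at VPD <= 0 (saturated air) the exponent -> 0, f_sm = 1.
    with np.errstate(invalid="ignore", divide="ignore"):
        f_sm = np.where(vpd > 0, rh ** (vpd / params.beta), 1.0)
        f_sm = np.where(np.isnan(vpd) | np.isnan(rh), np.nan, f_sm)
    f_m = np.clip(f_apar / fam, 0.0, 1.0)
    return ConstraintSet(
        f_wet=f_wet,
        f_g=f_g,
        f_t=f_t,
        f_m=f_m,
        f_sm=f_sm,
        f_apar=f_apar,
        f_ipar=f_ipar,
        delta=delta,
        vpd=vpd,
        f_apar_max=fam,
    )


def partition_radiation(rn, lai, k_rn):
    """Beer-Lambert split of net radiation into soil and canopy parts.

    R_ns = R_n exp(-k_Rn LAI), R_nc = R_n - R_ns; closure R_ns + R_nc = R_n
    holds exactly by construction.
    """
    rn = np.asarray(rn, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if not k_rn > 0:
        raise ValueError("k_rn must be positive")
    finite = np.isfinite(lai)
    if np.any(lai[finite] < 0):
        raise ValueError("lai must be >= 0")
    rns = rn * np.exp(-k_rn * lai)
    rnc = rn - rns
    return rns, rnc


def priestley_taylor_potential(ta, rn, g=0.0, alpha=ALPHA_PT, gamma=GAMMA_PSY):
    """Priestley-Taylor potential rate alpha * Delta/(Delta+gamma) * (Rn - G)."""
    delta = saturation_slope(ta)
    return alpha * delta / (delta + gamma) * (np.asarray(rn, float) - g)


def ptjpl_fluxes(
    ta, rh, lai, rn, params: BiomeParams, f_apar_max, g=0.0, t_opt=None
) -> FluxFields:
    """Evaluate the three PT-JPL flux components (W m^-2).

    Each component is floored at zero (negative available energy does not
    produce negative evaporation); ET is the sum of the floored components,
    so the closure ET = ES + EI + T holds exactly.  Missing forcing (NaN)
    yields missing fluxes.
    """
    cs = constraints(ta, rh, lai, params, f_apar_max, t_opt=t_opt)
    rns, rnc = partition_radiation(rn, lai, params.k_rn)
    pt = params.alpha * cs.delta / (cs.delta + params.gamma)
    g = np.asarray(g, dtype=float)
    es = (cs.f_wet + cs.f_sm * (1.0 - cs.f_wet)) * pt * (rns - g)
    ei = cs.f_wet * pt * rnc
    t = (1.0 - cs.f_wet) * cs.f_g * cs.f_t * cs.f_m * pt * rnc
    es = np.maximum(es, 0.0)
    ei = np.maximum(ei, 0.0)
    t = np.maximum(t, 0.0)
    et = es + ei + t
    return FluxFields(es=es, ei=ei, t=t, et=et)


def wm2_to_mm(flux_wm2, n_days=1.0):
    """Convert an energy flux (W m^-2, period mean) to mm of water per period.

    1 W m^-2 sustained over a day is 0.0864 MJ m^-2; dividing by the latent
    heat of vaporization (2.45 MJ kg^-1) gives kg m^-2 = mm of water.
    """
    return np.asarray(flux_wm2, float) * _WM2_TO_MJ_DAY / LAMBDA_MJ * n_days


def estimate_topt(ta, lai, f_apar, axis=0):
    """Optimum growth temperature: Ta at the maximum of LAI * Ta * f_APAR.

    The product is evaluated along ``axis`` (time); the earliest index wins
    ties (``argmax`` convention).  Entries where any input is missing are
    excluded; an all-missing series yields NaN.
    """
    ta = np.asarray(ta, float)
    lai = np.asarray(lai, float)
    f_apar = np.asarray(f_apar, float)
    prod = lai * ta * f_apar
    valid = np.isfinite(prod)
    score = np.where(valid, prod, -np.inf)
    idx = np.argmax(score, axis=axis)
    topt = np.take_along_axis(ta, np.expand_dims(idx, axis), axis=axis).squeeze(axis)
    any_valid = valid.any(axis=axis)
    return np.where(any_valid, topt, np.nan)


def estimate_fapar_max(f_apar, axis=0, floor=0.01):
    """Per-pixel maximum of f_APAR over the record, floored at ``floor``.

    The floor guards the division in f_m = f_APAR / f_APARmax on pixels
    that never green up.  All-missing series yield NaN.
    """
    f_apar = np.asarray(f_apar, float)
    valid = np.isfinite(f_apar)
    any_valid = valid.any(axis=axis)
    with np.errstate(all="ignore"):
        fam = np.nanmax(np.where(valid, f_apar, np.nan), axis=axis, initial=-np.inf)
    fam = np.maximum(fam, floor)
    return np.where(any_valid, fam, np.nan)


# --- biome parameter look-up table ------------------------------------------

def _params_from_mapping(d: dict) -> BiomeParams:
    return BiomeParams(
        b1=float(d.get("b1", 1.0)),
        b2=float(d.get("b2", 1.0)),
        k1=float(d["k1"]),
        k2=float(d["k2"]),
        t_opt=None if d.get("t_opt") is None else float(d["t_opt"]),
        beta=float(d["beta"]),
        k_rn=float(d.get("k_rn", 0.6)),
    )


def load_biome_params(path) -> dict[str, BiomeParams]:
    """Load a biome -> parameters look-up table from a YAML file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {biome: _params_from_mapping(d) for biome, d in raw.items()}


def save_biome_params(lut: dict[str, BiomeParams], path) -> None:
    """Write a biome parameter look-up table to YAML."""
    import yaml

    out = {
        biome: {
            "b1": float(p.b1),
            "b2": float(p.b2),
            "k1": float(p.k1),
            "k2": float(p.k2),
            "t_opt": None if p.t_opt is None else float(p.t_opt),
            "beta": float(p.beta),
            "k_rn": float(p.k_rn),
        }
        for biome, p in lut.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def default_biome_params() -> dict[str, BiomeParams]:
    """The packaged per-biome parameter look-up table.

    k1, k2 and beta are biome-specific calibrated values; b1, b2 default to
    1.0 and k_Rn to 0.6 (canonical PT-JPL values, not biome-calibrated);
    t_opt is None, meaning "derive per pixel from the forcing record".
    """
    from importlib.resources import files

    return load_biome_params(files("ptjplfuse.data") / "biome_params.yaml")
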