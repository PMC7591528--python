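"""Evaluation statistics: goodness-of-fit, nonparametric trend analysis,
and regional T/ET summaries.

``fit_stats`` reports R^2 (squared Pearson correlation, with the
1 - SSE/SST variant alongside), RMSE and RMSE relative to the observation
mean.  ``mann_kendall_sen`` is the Mann-Kendall monotonic-trend test with
tie-corrected variance and continuity correction plus Sen's slope (median
of all pairwise slopes).  ``regional_tet`` computes the regional T/ET as
the ratio of regional means — the statistically sound aggregate — with the
mean of per-pixel ratios reported alongside for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ptjpl import TET_EPSILON

__all__ = [
    "FitStats",
    "TrendResult",
    "RegionalTET",
    "fit_stats",
    "mann_kendall_sen",
    "grid_trend",
    "regional_tet",
]


@dataclass(frozen=True)
class FitStats:
    """Goodness-of-fit between simulated and observed series."""

    r2: float            # squared Pearson correlation
    r2_sse: float        # 1 - SSE/SST variant
    rmse: float
    rel_rmse: float      # percent of the observation mean
    n: int
    degenerate: bool     # zero variance in either series (r2 undefined)


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall test + Sen's slope for an annual series."""

    sen_slope: float
    mk_s: int
    mk_z: float
    p_value: float
    significant: bool
    alpha: float
    n: int


@dataclass(frozen=True)
class RegionalTET:
    """Regional T/ET: ratio of means (headline) vs mean of ratios."""

    ratio_of_means: float
    mean_of_ratios: float
    n_valid: int


def fit_stats(sim, obs) -> FitStats:
    """Compute R^2, RMSE and relative RMSE over finite pairs.

    rel_rmse = 100 * RMSE / mean(obs).  If either series has zero variance
    the correlation is undefined: r2 is NaN and ``degenerate`` is set.
    """
    sim = np.asarray(sim, float).ravel()
    obs = np.asarray(obs, float).ravel()
    if sim.shape != obs.shape:
        raise ValueError("sim and obs must have the same length")
    ok = np.isfinite(sim) & np.isfinite(obs)
    sim, obs = sim[ok], obs[ok]
    n = sim.size
    if n < 2:
        raise ValueError("need at least 2 finite pairs")
    resid = sim - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    obs_mean = float(np.mean(obs))
    rel_rmse = float(100.0 * rmse / obs_mean) if obs_mean != 0 else np.nan
    sst = float(np.sum((obs - obs_mean) ** 2))
    degenerate = np.var(sim) == 0 or np.var(obs) == 0
    if degenerate:
        r2 = np.nan
    else:
        r = np.corrcoef(sim, obs)[0, 1]
        r2 = float(r * r)
    r2_sse = float(1.0 - np.sum(resid**2) / sst) if sst > 0 else np.nan
    return FitStats(
        r2=r2, r2_sse=r2_sse, rmse=rmse, rel_rmse=rel_rmse, n=n,
        degenerate=bool(degenerate),
    )


def _mk_variance(x: np.ndarray) -> float:
    """Tie-corrected variance of the Mann-Kendall S statistic."""
    n = x.size
    var = n * (n - 1) * (2 * n + 5)
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var -= np.sum(ties * (ties - 1) * (2 * ties + 5))
    return var / 18.0


def mann_kendall_sen(series, alpha: float = 0.01) -> TrendResult:
    """Mann-Kendall trend test and Sen's slope for an annual series.

    S = sum over i<j of sign(x_j - x_i); the standardized statistic uses
    the tie-corrected variance and a continuity correction; the two-sided
    p-value comes from the normal approximation.  Sen's slope is the
    median of all pairwise slopes (x_j - x_i) / (j - i).
    """
    x = np.asarray(series, float).ravel()
    x = x[np.isfinite(x)]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 values for a trend test")
    diff_sign = np.sign(x[None, :] - x[:, None])
    iu = np.triu_indices(n, k=1)
    s = int(diff_sign[iu].sum())
    idx = np.arange(n, dtype=float)
    slopes = (x[None, :] - x[:, None])[iu] / (idx[None, :] - idx[:, None])[iu]
    sen = float(np.median(slopes))
    var = _mk_variance(x)
    if var <= 0:  # constant series
        return TrendResult(sen_slope=0.0, mk_s=s, mk_z=0.0, p_value=1.0,
                           significant=False, alpha=alpha, n=n)
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TrendResult(
        sen_slope=sen, mk_s=s, mk_z=float(z), p_value=p,
        significant=bool(p < alpha), alpha=alpha, n=n,
    )


def grid_trend(values: np.ndarray, alpha: float = 0.01):
    """Per-pixel Sen slope and MK p-value over a (years, lat, lon) stack.

    Pixels with fewer than 4 valid years are NaN.
    """
    ny, nlat, nlon = values.shape
    slope = np.full((nlat, nlon), np.nan)
    pval = np.full((nlat, nlon), np.nan)
    for i in range(nlat):
        for j in range(nlon):
            series = values[:, i, j]
            if np.isfinite(series).sum() < 4:
                continue
            res = mann_kendall_sen(series, alpha=alpha)
            slope[i, j] = res.sen_slope
            pval[i, j] = res.p_value
    return slope, pval


def regional_tet(t, et, mask=None, epsilon: float = TET_EPSILON) -> RegionalTET:
    """Regional T/ET over valid masked cells.

    The headline value is mean(T) / mean(ET) over the valid cells; the
    per-pixel mean of T/ET is reported alongside because it over-weights
    low-flux pixels and is discouraged as a regional summary.
    """
    t = np.asarray(t, float)
    et = np.asarray(et, float)
    valid = np.isfinite(t) & np.isfinite(et)
    if mask is not None:
        valid &= np.asarray(mask, bool)
    if not valid.any():
        raise ValueError("no valid cells in the region")
    tv, etv = t[valid], et[valid]
    mean_et = float(np.mean(etv))
    rom = float(np.mean(tv) / mean_et) if mean_et > epsilon else np.nan
    ratio_ok = etv > epsilon
    mor = float(np.mean(tv[ratio_ok] / etv[ratio_ok])) if ratio_ok.any() else np.nan
    return RegionalTET(ratio_of_means=rom, mean_of_ratios=mor, n_valid=int(valid.sum()))
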