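"""Variance-based (Sobol') global sensitivity analysis.

Implements the Saltelli cross-sampling design and the standard estimators
for the first-order index S_m = V_m / V, the closed second-order index
S_mn = V_mn / V, and the total-order index S_Tm = 1 - V_~m / V:

* base samples from a scrambled Sobol' low-discrepancy sequence
  (scipy.stats.qmc), split into matrices A and B plus the radial matrices
  A_B^(i) (A with column i from B) and B_A^(i);
* S_m via the Saltelli (2010) estimator  V_m ~ mean(y_B (y_AB_m - y_A));
* S_Tm via the Jansen estimator          V_~m-complement ~ mean((y_A - y_AB_m)^2)/2;
* S_mn via the closed second-order identity
  V_mn^closed ~ mean(y_BA_m y_AB_n) - mean(y_A) mean(y_B), S_mn = V_mn^closed/V - S_m - S_n.

Indices are reported as estimated (negative estimates are not clipped) with
bootstrap confidence intervals from resampling design rows, so statistical
zero is distinguishable from bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

__all__ = [
    "ParameterSpace",
    "SobolDesign",
    "SobolResult",
    "sample_matrices",
    "evaluate_design",
    "sobol_indices",
    "rank_sensitive",
    "DEFAULT_BOUNDS",
]

#: Default calibration/sensitivity bounds for the seven PT-JPL parameters.
DEFAULT_BOUNDS = {
    "b1": (0.5, 1.0),
    "b2": (0.5, 1.0),
    "k1": (0.1, 1.5),
    "k2": (0.1, 1.5),
    "t_opt": (5.0, 35.0),
    "beta": (0.1, 3.0),
    "k_rn": (0.2, 1.0),
}


@dataclass(frozen=True)
class ParameterSpace:
    """An ordered set of parameters with box bounds."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lower", np.asarray(self.lower, float))
        object.__setattr__(self, "upper", np.asarray(self.upper, float))
        if len(self.names) != self.lower.size or len(self.names) != self.upper.size:
            raise ValueError("names/bounds length mismatch")
        if np.any(self.lower >= self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def d(self) -> int:
        return len(self.names)

    def scale(self, u: np.ndarray) -> np.ndarray:
        """Map unit-cube samples into the box."""
        return self.lower + np.asarray(u) * (self.upper - self.lower)

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        return np.all((theta >= self.lower) & (theta <= self.upper), axis=-1)

    @classmethod
    def from_names(cls, names, bounds: dict | None = None) -> "ParameterSpace":
        """Build a space from parameter names using default (or given) bounds."""
        bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
        lo = [bounds[n][0] for n in names]
        hi = [bounds[n][1] for n in names]
        return cls(tuple(names), np.array(lo), np.array(hi))


@dataclass(frozen=True)
class SobolDesign:
    """Saltelli cross-sampling design: n_base * (2d + 2) model evaluations."""

    space: ParameterSpace
    n_base: int
    seed: int
    a: np.ndarray        # (n, d)
    b: np.ndarray        # (n, d)
    ab: np.ndarray       # (d, n, d): A with column i replaced from B
    ba: np.ndarray       # (d, n, d): B with column i replaced from A

    @property
    def n_rows(self) -> int:
        return self.n_base * (2 * self.space.d + 2)

    def all_rows(self) -> np.ndarray:
        """Stack every design row for batched model evaluation."""
        d, n = self.space.d, self.n_base
        return np.concatenate(
            [self.a, self.b, self.ab.reshape(d * n, d), self.ba.reshape(d * n, d)]
        )


@dataclass
class SobolEvaluations:
    y_a: np.ndarray
    y_b: np.ndarray
    y_ab: np.ndarray  # (d, n)
    y_ba: np.ndarray  # (d, n)


@dataclass
class SobolResult:
    """Estimated Sobol' indices with bootstrap confidence intervals."""

    names: tuple[str, ...]
    s1: np.ndarray
    st: np.ndarray
    s2: np.ndarray          # (d, d) symmetric, NaN on the diagonal
    s1_ci: np.ndarray       # (d, 2) bootstrap percentile interval
    st_ci: np.ndarray
    s1_se: np.ndarray
    st_se: np.ndarray
    n_base: int
    seed: int


def sample_matrices(space: ParameterSpace, n_base: int, seed: int) -> SobolDesign:
    """Draw the Saltelli design from a scrambled Sobol' sequence.

    A power-of-two ``n_base`` preserves the balance of the Sobol' sequence
    (recommended, not enforced).
    """
    if n_base < 2:
        raise ValueError("n_base must be >= 2")
    d = space.d
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
    u = sampler.random(n_base)
    a = space.scale(u[:, :d])
    b = space.scale(u[:, d:])
    ab = np.repeat(a[None, :, :], d, axis=0)
    ba = np.repeat(b[None, :, :], d, axis=0)
    for i in range(d):
        ab[i, :, i] = b[:, i]
        ba[i, :, i] = a[:, i]
    return SobolDesign(space=space, n_base=n_base, seed=seed, a=a, b=b, ab=ab, ba=ba)


def evaluate_design(design: SobolDesign, model, vectorized: bool = True) -> SobolEvaluations:
    """Run a model over the design.

    ``model`` maps (n, d) parameter rows to an (n,) output if vectorized,
    otherwise a single row to a scalar.
    """
    rows = design.all_rows()
    if vectorized:
        y = np.asarray(model(rows), float)
    else:
        y = np.array([float(model(r)) for r in rows])
    if y.shape != (rows.shape[0],):
        raise ValueError("model output must be one scalar per design row")
    d, n = design.space.d, design.n_base
    y_a = y[:n]
    y_b = y[n : 2 * n]
    y_ab = y[2 * n : 2 * n + d * n].reshape(d, n)
    y_ba = y[2 * n + d * n :].reshape(d, n)
    return SobolEvaluations(y_a=y_a, y_b=y_b, y_ab=y_ab, y_ba=y_ba)


def _point_estimates(y_a, y_b, y_ab, y_ba):
    var = np.var(np.concatenate([y_a, y_b]), ddof=0)
    if var <= 0:
        raise ValueError("zero output variance: model is constant over the design")
    s1 = np.mean(y_b[None, :] * (y_ab - y_a[None, :]), axis=1) / var
    st = 0.5 * np.mean((y_a[None, :] - y_ab) ** 2, axis=1) / var
    d = y_ab.shape[0]
    s2 = np.full((d, d), np.nan)
    f0sq = np.mean(y_a) * np.mean(y_b)
    for m in range(d):
        for nn in range(m + 1, d):
            v_closed = np.mean(y_ba[m] * y_ab[nn]) - f0sq
            val = v_closed / var - s1[m] - s1[nn]
            s2[m, nn] = s2[nn, m] = val
    return s1, st, s2


def sobol_indices(
    design: SobolDesign,
    evals: SobolEvaluations,
    n_boot: int = 200,
    ci_level: float = 0.95,
    boot_seed: int = 0,
) -> SobolResult:
    """Estimate first-, second- and total-order indices with bootstrap CIs."""
    y_a, y_b, y_ab, y_ba = evals.y_a, evals.y_b, evals.y_ab, evals.y_ba
    s1, st, s2 = _point_estimates(y_a, y_b, y_ab, y_ba)
    n = y_a.size
    rng = np.random.default_rng(boot_seed)
    s1_boot = np.empty((n_boot, design.space.d))
    st_boot = np.empty((n_boot, design.space.d))
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            b1, bt, _ = _point_estimates(
                y_a[idx], y_b[idx], y_ab[:, idx], y_ba[:, idx]
            )
        except ValueError:  # degenerate resample
            b1 = np.full(design.space.d, np.nan)
            bt = np.full(design.space.d, np.nan)
        s1_boot[k] = b1
        st_boot[k] = bt
    alpha = (1.0 - ci_level) / 2.0
    qs = [100 * alpha, 100 * (1 - alpha)]
    s1_ci = np.nanpercentile(s1_boot, qs, axis=0).T
    st_ci = np.nanpercentile(st_boot, qs, axis=0).T
    return SobolResult(
        names=design.space.names,
        s1=s1,
        st=st,
        s2=s2,
        s1_ci=s1_ci,
        st_ci=st_ci,
        s1_se=np.nanstd(s1_boot, axis=0),
        st_se=np.nanstd(st_boot, axis=0),
        n_base=design.n_base,
        seed=design.seed,
    )


def rank_sensitive(result: SobolResult, threshold: float = 0.05) -> list[str]:
    """Parameters whose total-order index meets the threshold, most
    sensitive first; ties broken alphabetically for determinism."""
    keep = [(st, name) for name, st in zip(result.names, result.st) if st >= threshold]
    keep.sort(key=lambda p: (-p[0], p[1]))
    return [name for _, name in keep]
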