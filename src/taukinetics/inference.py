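"""Replication-rate inference from seed and aggregate time courses.

The measured signal is modelled by the rescaled logistic solution of the
replication-limited regime,

    S(t) = alpha f0 e^{kappa t} / (1 - f0 + f0 e^{kappa t}),

with Gaussian noise on log10 S whose SD is fixed from replicate scatter. The
posterior over (kappa, f0, alpha) is evaluated on a dense grid with a 1/x
prior on kappa and f0 (uniform in log) and a flat prior on alpha, then
marginalized to a 1-D kappa posterior. Brain regions are analyzed separately
and their marginals combined by pointwise product; the same product combines
datasets measured by different assays into an overall kappa.

A least-squares fit to per-time medians is provided for display parity with
the Bayesian estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import logistic_fraction

__all__ = [
    "MeasurementSet",
    "GridSpec",
    "PosteriorGrid",
    "KappaPosterior",
    "PosteriorSummary",
    "estimate_noise_sd",
    "posterior_grid",
    "marginal_kappa",
    "combine_marginals",
    "lsq_median_fit",
    "infer_dataset_kappa",
]


@dataclass
class MeasurementSet:
    """Long-format assay measurements feeding the kappa inference.

    Columns: subject, region, time_years (or stage mapped to time upstream),
    value (assay units, positive), assay; optional replicate group ids.
    """

    df: pd.DataFrame

    REQUIRED = ("subject", "region", "time_years", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"MeasurementSet missing columns: {missing}")
        if (self.df["value"] <= 0).any():
            raise ValueError("values must be positive (log-transformable)")
        if not np.isfinite(self.df["time_years"]).all():
            raise ValueError("times must be finite")
        if self.df["time_years"].nunique() < 2:
            raise ValueError("need at least 2 distinct time points")

    @classmethod
    def from_csv(cls, path) -> "MeasurementSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def regions(self) -> list:
        return sorted(self.df["region"].unique())


@dataclass(frozen=True)
class GridSpec:
    """Posterior grid resolution and bounds.

    kappa and f0 axes are log-spaced (so the 1/x prior is uniform mass per
    node); alpha is linear. f0 bounds span one seed per brain (1e-10) up to
    1% of the final concentration (0.01).
    """

    n_kappa: int = 240
    kappa_bounds: tuple = (1e-3, 10.0)
    n_f0: int = 80
    f0_bounds: tuple = (1e-10, 1e-2)
    n_alpha: int = 60
    alpha_bounds: Optional[tuple] = None  # default: [max obs, 100 * max obs]

    def axes(self, max_value: float):
        kappa = np.geomspace(*self.kappa_bounds, self.n_kappa)
        f0 = np.geomspace(*self.f0_bounds, self.n_f0)
        ab = self.alpha_bounds or (max_value, 100.0 * max_value)
        alpha = np.linspace(*ab, self.n_alpha)
        return kappa, f0, alpha


@dataclass
class PosteriorGrid:
    """Normalized posterior mass over the (kappa, f0, alpha) grid."""

    kappa_axis: np.ndarray
    f0_axis: np.ndarray
    alpha_axis: np.ndarray
    density: np.ndarray  # shape (n_kappa, n_f0, n_alpha), sums to 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.density.sum() - 1.0) > 1e-9:
            raise ValueError("posterior mass must sum to 1")
        if (self.density < 0).any():
            raise ValueError("posterior mass must be nonnegative")


@dataclass
class KappaPosterior:
    """1-D posterior over the replication rate on a log-spaced grid."""

    kappa_axis: np.ndarray
    mass: np.ndarray  # sums to 1

    def __post_init__(self) -> None:
        self.kappa_axis = np.asarray(self.kappa_axis, float)
        self.mass = np.asarray(self.mass, float)
        s = self.mass.sum()
        if not np.isfinite(s) or s <= 0:
            raise ValueError("posterior mass must be positive and finite")
        self.mass = self.mass / s

    @property
    def mean(self) -> float:
        return float(np.sum(self.kappa_axis * self.mass))

    @property
    def sd(self) -> float:
        m = self.mean
        return float(np.sqrt(np.sum((self.kappa_axis - m) ** 2 * self.mass)))

    def credible_interval(self, level: float = 0.95) -> tuple:
        cdf = np.cumsum(self.mass)
        lo = (1.0 - level) / 2.0
        return (float(np.interp(lo, cdf, self.kappa_axis)),
                float(np.interp(1.0 - lo, cdf, self.kappa_axis)))

    def summary(self) -> "PosteriorSummary":
        return PosteriorSummary(mean=self.mean, sd=self.sd,
                                ci95=self.credible_interval(0.95))


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    sd: float
    ci95: tuple


def estimate_noise_sd(measurements: MeasurementSet,
                      group_cols: Sequence[str] = ("subject", "region", "time_years"),
                      ) -> float:
    """Pooled within-replicate SD of log10 signal.

    Replicate groups are rows sharing ``group_cols`` (plus an explicit
    'replicate' column if present, which then defines the grouping). Pools
    the within-group sum of squares over all groups of size >= 2.
    """
    import warnings as _warnings

    df = measurements.df
    cols = [c for c in group_cols if c in df.columns]
    logv = np.log10(df["value"].to_numpy())
    g = df.assign(_log=logv).groupby(cols)["_log"]
    sizes = g.size()
    if (sizes < 2).all():
        raise ValueError(
            "no replicate groups of size >= 2; pass an explicit noise SD in config")
    ss = g.apply(lambda x: float(((x - x.mean()) ** 2).sum()))
    valid = sizes >= 2
    dof = int((sizes[valid] - 1).sum())
    sd = float(np.sqrt(ss[valid].sum() / dof))
    if sd == 0.0:
        _warnings.warn("all replicates identical: noise SD estimate is 0 (degenerate)")
    return sd


def _log_likelihood_grid(times, log_values, kappa, f0, alpha, sigma):
    """Gaussian log-likelihood of log10 S(t) on the (kappa, f0, alpha) grid.

    Exploits that log10 S = log10 alpha + log10 f(t; kappa, f0): expanding the
    squared residual gives per-(kappa, f0) sufficient statistics that combine
    with the alpha axis analytically, avoiding a full 3-D times-data loop.
    """
    K, F = np.meshgrid(kappa, f0, indexing="ij")
    uniq_t, inv = np.unique(times, return_inverse=True)
    # log10 f at each unique time for every (kappa, f0)
    logf = np.empty((len(uniq_t),) + K.shape)
    for i, t in enumerate(uniq_t):
        # stable logistic in log space
        z = K * t
        log_num = np.log(F) + z
        log_den = np.logaddexp(np.log1p(-F), np.log(F) + z)
        logf[i] = (log_num - log_den) / np.log(10.0)
    a = logf[inv] - log_values[:, None, None]        # residual minus log10 alpha
    A0 = np.sum(a * a, axis=0)                        # (nk, nf)
    A1 = np.sum(a, axis=0)
    N = len(times)
    c = np.log10(alpha)                               # (na,)
    # sum_i (a_i + c)^2 = A0 + 2 c A1 + N c^2
    sq = (A0[..., None] + 2.0 * c[None, None, :] * A1[..., None]
          + N * c[None, None, :] ** 2)
    return -sq / (2.0 * sigma**2)


def posterior_grid(measurements: MeasurementSet, sigma: float,
                   grid_spec: Optional[GridSpec] = None,
                   region: Optional[str] = None) -> PosteriorGrid:
    """Grid posterior over (kappa, f0, alpha) for one region's measurements.

    The prior is 1/kappa * 1/f0 * flat(alpha) restricted to the grid bounds;
    on log-spaced kappa/f0 axes this is uniform prior mass per node, times
    trapezoidal cell widths on the linear alpha axis. A warning is recorded
    in the result metadata when > 1% of posterior mass sits on the grid
    boundary (the grid may then be too narrow).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    spec = grid_spec or GridSpec()
    df = measurements.df
    if region is not None:
        df = df[df["region"] == region]
        if df.empty:
            raise ValueError(f"no measurements for region {region!r}")
    times = df["time_years"].to_numpy(float)
    log_values = np.log10(df["value"].to_numpy(float))
    kappa, f0, alpha = spec.axes(max_value=float(df["value"].max()))

    ll = _log_likelihood_grid(times, log_values, kappa, f0, alpha, sigma)
    # prior mass: uniform per node in log kappa, log f0; trapezoid widths in alpha
    w_alpha = np.gradient(alpha)
    log_mass = ll + np.log(w_alpha)[None, None, :]
    log_mass -= log_mass.max()
    mass = np.exp(log_mass)
    mass /= mass.sum()

    meta = {"sigma": sigma, "n_obs": len(times), "region": region}
    edge = (mass[0].sum() + mass[-1].sum()
            + mass[:, 0].sum() + mass[:, -1].sum())
    if edge > 0.01:
        meta["warning"] = ("more than 1% of posterior mass on the kappa/f0 "
                           "grid boundary; consider widening the grid")
    return PosteriorGrid(kappa_axis=kappa, f0_axis=f0, alpha_axis=alpha,
                         density=mass, meta=meta)


def marginal_kappa(grid: PosteriorGrid) -> KappaPosterior:
    """Marginalize the grid posterior over f0 and alpha."""
    return KappaPosterior(kappa_axis=grid.kappa_axis,
                          mass=grid.density.sum(axis=(1, 2)))


def combine_marginals(posteriors: Sequence[KappaPosterior]) -> KappaPosterior:
    """Combine independent kappa marginals by pointwise product.

    Posteriors on different grids are resampled onto the first posterior's
    grid by linear interpolation of mass density. Raises if the product has
    no support overlap.
    """
    if not posteriors:
        raise ValueError("need at least one posterior")
    ref = posteriors[0]
    prod = ref.mass.copy()
    for p in posteriors[1:]:
        if (p.kappa_axis.shape == ref.kappa_axis.shape
                and np.allclose(p.kappa_axis, ref.kappa_axis)):
            m = p.mass
        else:
            m = np.interp(ref.kappa_axis, p.kappa_axis, p.mass, left=0.0, right=0.0)
        prod = prod * m
    if prod.sum() <= 0:
        raise ValueError("posteriors have disjoint support; zero evidence overlap")
    return KappaPosterior(kappa_axis=ref.kappa_axis, mass=prod)


def infer_dataset_kappa(measurements: MeasurementSet, sigma: Optional[float] = None,
                        grid_spec: Optional[GridSpec] = None,
                        per_region: bool = True) -> dict:
    """Full per-dataset inference: per-region grids -> marginals -> combined kappa.

    Returns a dict with the combined :class:`KappaPosterior`, its summary and
    the per-region marginals.
    """
    if sigma is None:
        sigma = estimate_noise_sd(measurements)
    regions = measurements.regions if per_region else [None]
    marginals, region_names = [], []
    for r in regions:
        grid = posterior_grid(measurements, sigma, grid_spec, region=r)
        marginals.append(marginal_kappa(grid))
        region_names.append(r)
    combined = combine_marginals(marginals)
    return {
        "combined": combined,
        "summary": combined.summary(),
        "per_region": dict(zip(region_names, marginals)),
        "sigma": sigma,
    }


def lsq_median_fit(times, medians, p0: Optional[tuple] = None) -> dict:
    """Least-squares logistic fit to per-time medians in log10 signal space.

    Fits (kappa, f0, alpha) of S(t) = alpha f(t; kappa, f0) to
    log10(medians); the display-parity counterpart of the Bayesian scheme.
    Returns the point estimate and residual trace.
    """
    times = np.asarray(times, float)
    medians = np.asarray(medians, float)
    if times.size < 3:
        raise ValueError("need at least 3 time points")
    if (medians <= 0).any():
        raise ValueError("medians must be positive")
    logy = np.log10(medians)

    def resid(theta):
        lk, lf0, la = theta
        f = logistic_fraction(times, 10.0 ** lk, 10.0 ** lf0)
        return np.log10((10.0 ** la) * f) - logy

    if p0 is None:
        p0 = (np.log10(0.2), -4.0, np.log10(medians.max() * 2.0))
    res = least_squares(resid, p0, bounds=([-4, -10, -12], [1.5, np.log10(0.5), 12]),
                        xtol=1e-14, ftol=1e-14)
    if not res.success:
        raise RuntimeError(f"median fit did not converge: {res.message}; "
                           f"residuals {res.fun}")
    kappa, f0, alpha = 10.0 ** res.x
    return {"kappa": float(kappa), "f0": float(f0), "alpha": float(alpha),
            "residual": float(np.sum(res.fun ** 2))}
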