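"""Closed-form kinetic quantities for seed replication.

Logistic (replication-limited) growth of the seed fraction, doubling times,
the growth/multiplication decomposition of the effective replication rate,
fibril-size arithmetic and the regime-threshold / unit-conversion helpers
used when comparing effective diffusion constants across geometries.

All human-data rates are per year; mouse rates are per month. Every function
is a pure scalar/ndarray computation with no state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

__all__ = [
    "KineticParams",
    "RateDecomposition",
    "logistic_fraction",
    "signal_from_fraction",
    "doubling_time",
    "half_occupancy_time",
    "fold_increase",
    "decompose_rates",
    "recombine_rates",
    "fibril_monomer_count",
    "critical_diffusion",
    "front_speed",
    "round_sig",
    "m2_per_year_to_m2_per_second",
    "m2_per_second_to_m2_per_year",
    "regions2_to_m2",
    "m2_to_regions2",
    "SECONDS_PER_YEAR",
]

#: Length of a year (365.25 days) in seconds, used for all m²/yr ↔ m²/s conversions.
SECONDS_PER_YEAR = 365.25 * 24 * 3600.0  # 3.15576e7 s

#: Beta-sheet layer spacing along a tau fibril axis, nm.
BETA_SHEET_SPACING_NM = 0.47


@dataclass(frozen=True)
class KineticParams:
    """Parameter bundle of the spreading + replication model.

    Attributes
    ----------
    kappa : float
        Effective replication rate (per year; per month for mouse data).
    D : float
        Effective diffusion coefficient (length² / time).
    f0 : float
        Initial seed fraction (dimensionless, in (0, 1)).
    alpha : float
        Proportionality constant converting seed fraction to the measured
        signal (assay units).
    b : float
        Additive signal baseline (assay units; nonzero for PET SUVr).
    P_max : float
        Maximal seed concentration in measured units.
    units : str
        Unit string for ``kappa`` ("per_year" or "per_month").
    """

    kappa: float
    D: float = 0.0
    f0: float = 1e-4
    alpha: float = 1.0
    b: float = 0.0
    P_max: float = 1.0
    units: str = "per_year"

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if not (0.0 < self.f0 < 1.0):
            raise ValueError(f"f0 must lie in (0, 1), got {self.f0}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.b < 0:
            raise ValueError(f"b must be nonnegative, got {self.b}")
        if self.D < 0:
            raise ValueError(f"D must be nonnegative, got {self.D}")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "KineticParams":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class RateDecomposition:
    """Growth/multiplication decomposition of a replication rate.

    The effective replication rate is the geometric mean of the growth and
    multiplication rates, kappa = sqrt(k_growth * k_mult), while the mean
    aggregate size (in monomers) is their ratio, mu = sqrt(k_growth / k_mult).
    """

    k_growth: float
    k_mult: float
    mu: float

    def __post_init__(self) -> None:
        if not (self.k_growth > 0 and self.k_mult > 0 and self.mu > 0):
            raise ValueError("all decomposition fields must be positive")

    @property
    def kappa(self) -> float:
        """Recombined replication rate sqrt(k_growth * k_mult)."""
        return math.sqrt(self.k_growth * self.k_mult)


def logistic_fraction(t, kappa: float, f0: float):
    """Seed fraction f(t) under replication-limited (logistic) growth.

    f(t) = f0 e^{kappa t} / (1 - f0 + f0 e^{kappa t}),
    the solution of df/dt = kappa f (1 - f) with f(0) = f0.

    Parameters
    ----------
    t : float or array-like
        Time, in the inverse units of ``kappa``.
    kappa : float
        Replication rate. May be zero or negative (decay); must be finite.
    f0 : float
        Initial fraction, strictly inside (0, 1).

    Returns
    -------
    float or ndarray in (0, 1).
    """
    if not np.isfinite(kappa):
        raise ValueError("kappa must be finite")
    if not (0.0 < f0 < 1.0):
        raise ValueError(f"f0 must lie in (0, 1), got {f0}")
    t = np.asarray(t, dtype=float)
    # stable form: 1 / (1 + ((1-f0)/f0) exp(-kappa t)) avoids overflow at large kt
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + ((1.0 - f0) / f0) * np.exp(-kappa * t))
    return out if out.ndim else float(out)


def signal_from_fraction(f, alpha: float, b: float = 0.0):
    """Convert a seed fraction to a measured signal: S = alpha * f + b."""
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    if b < 0:
        raise ValueError("b must be nonnegative")
    f = np.asarray(f, dtype=float)
    out = alpha * f + b
    return out if out.ndim else float(out)


def doubling_time(kappa: float) -> float:
    """Time for the seed number to double, t2 = ln(2)/kappa."""
    if not kappa > 0:
        raise ValueError(f"doubling time requires kappa > 0, got {kappa}")
    return math.log(2.0) / kappa


def half_occupancy_time(kappa: float, f0: float) -> float:
    """Time at which the logistic fraction reaches 1/2: ln((1-f0)/f0)/kappa."""
    if not kappa > 0:
        raise ValueError("kappa must be positive")
    if not (0.0 < f0 < 1.0):
        raise ValueError("f0 must lie in (0, 1)")
    return math.log((1.0 - f0) / f0) / kappa


def fold_increase(kappa: float, t: float) -> float:
    """Exponential-phase fold increase of the seed number, e^{kappa t}."""
    return math.exp(kappa * t)


def decompose_rates(kappa: float, mu: float) -> RateDecomposition:
    """Split a replication rate into growth and multiplication rates.

    Given the mean aggregate size mu (monomers), k_growth = mu * kappa and
    k_mult = kappa / mu, so that kappa and mu are recovered as the geometric
    mean and ratio respectively.
    """
    if not kappa > 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if not mu >= 1:
        raise ValueError(f"mu must be >= 1 monomer, got {mu}")
    return RateDecomposition(k_growth=mu * kappa, k_mult=kappa / mu, mu=mu)


def recombine_rates(k_growth: float, k_mult: float) -> tuple[float, float]:
    """Inverse of :func:`decompose_rates`: return (kappa, mu)."""
    if not (k_growth > 0 and k_mult > 0):
        raise ValueError("rates must be positive")
    return math.sqrt(k_growth * k_mult), math.sqrt(k_growth / k_mult)


def fibril_monomer_count(
    length_nm: float,
    layer_spacing_nm: float = BETA_SHEET_SPACING_NM,
    monomers_per_layer: int = 2,
) -> int:
    """Number of monomers in a fibril of the given length.

    Stacks ``monomers_per_layer`` monomers every ``layer_spacing_nm`` along
    the fibril axis and rounds to the nearest whole monomer.
    """
    if length_nm <= 0 or layer_spacing_nm <= 0 or monomers_per_layer <= 0:
        raise ValueError("all fibril geometry inputs must be positive")
    return int(round(monomers_per_layer * length_nm / layer_spacing_nm))


def critical_diffusion(kappa: float, r_max: float, ratio: float = 0.0025) -> float:
    """Diffusion coefficient at the spreading/replication regime boundary.

    For a compact initial seed distribution the switch between regimes occurs
    near D/kappa = 0.0025 r_max²; this returns ``ratio * kappa * r_max²`` in
    units consistent with the inputs (``ratio`` can be set to a fitted D/kappa
    ratio such as 0.1 to convert it to a diffusion coefficient).
    """
    if kappa <= 0 or r_max <= 0:
        raise ValueError("kappa and r_max must be positive")
    return ratio * kappa * r_max**2


def front_speed(D: float, kappa: float) -> float:
    """Asymptotic pulled-front speed of the FKPP equation, v = 2 sqrt(D kappa)."""
    if D <= 0 or kappa <= 0:
        raise ValueError("D and kappa must be positive")
    return 2.0 * math.sqrt(D * kappa)


def m2_per_year_to_m2_per_second(d: float) -> float:
    """Convert a diffusion coefficient from m²/yr to m²/s."""
    return d / SECONDS_PER_YEAR


def m2_per_second_to_m2_per_year(d: float) -> float:
    """Convert a diffusion coefficient from m²/s to m²/yr."""
    return d * SECONDS_PER_YEAR


def regions2_to_m2(d: float, r_max_m: float = 0.1, n_regions: int = 6) -> float:
    """Convert a diffusion coefficient from regions²/time to m²/time.

    One "region" is one spacing of the sampled-region chain; with the whole
    path spanning ``r_max_m`` metres over ``n_regions`` regions, a region is
    r_max_m / n_regions metres.
    """
    if r_max_m <= 0 or n_regions <= 0:
        raise ValueError("r_max_m and n_regions must be positive")
    return d * (r_max_m / n_regions) ** 2


def m2_to_regions2(d: float, r_max_m: float = 0.1, n_regions: int = 6) -> float:
    """Convert a diffusion coefficient from m²/time to regions²/time."""
    if r_max_m <= 0 or n_regions <= 0:
        raise ValueError("r_max_m and n_regions must be positive")
    return d / (r_max_m / n_regions) ** 2


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention for reported rates)."""
    if x == 0:
        return 0.0
    if sig < 1:
        raise ValueError("sig must be >= 1")
    exponent = math.floor(math.log10(abs(x)))
    q = round(x, -exponent + sig - 1)
    return q
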