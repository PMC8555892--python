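"""Longitudinal tau-PET rate analysis.

Two SUVr measurements about two years apart per individual give an annual
rate of signal change r = dS/dt. If the underlying tau load follows the
shifted logistic S(t) = alpha f(t) + b, differentiating gives

    r = (kappa / alpha) (S - b) (alpha - (S - b)),

an inverted parabola in S with roots at the baseline b and the plateau
alpha + b and maximum kappa * alpha / 4 at its midpoint. Fitting this rate-
vs-signal relation across a cohort yields the replication rate kappa without
any Braak-stage time calibration: the clock is real elapsed time between
scans. The signal scale alpha is bounded above by 4 SUVr (a conservative
plateau well beyond observed signals); kappa and b are positive and free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["PETRecord", "PETFit", "annual_rate", "rate_model", "fit_pet",
           "records_from_frame"]

#: Conservative upper bound on the SUVr span of the sigmoid (plateau minus baseline).
ALPHA_MAX = 4.0


@dataclass(frozen=True)
class PETRecord:
    """One individual's visit pair: signals S1, S2 and the interval in years."""

    S1: float
    S2: float
    interval: float
    group: Optional[str] = None  # AD / MCI / CN PiB+ / CN PiB-

    def __post_init__(self) -> None:
        if self.S1 <= 0 or self.S2 <= 0:
            raise ValueError("SUVr signals must be positive")
        if self.interval <= 0:
            raise ValueError("interval must be positive")


@dataclass
class PETFit:
    """Fitted (kappa, alpha, b) of the rate-vs-signal parabola.

    ``alpha_max`` is the signal-span bound the fit was run under (4 SUVr by
    default; a looser bound may be requested for sensitivity checks).
    """

    kappa: float
    alpha: float
    b: float
    residual: float = float("nan")
    alpha_at_bound: bool = False
    degenerate: bool = False
    alpha_max: float = ALPHA_MAX

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.b <= 0:
            raise ValueError("kappa and b must be positive")
        if not (0 < self.alpha <= self.alpha_max + 1e-9):
            raise ValueError(f"alpha must lie in (0, {self.alpha_max}]")


def annual_rate(record: PETRecord) -> tuple[float, float]:
    """(S_avg, r): mean signal over the two visits and annualized change.

    S is approximated by the average of the two consecutive measurements;
    r = (S2 - S1) / interval.
    """
    s_avg = 0.5 * (record.S1 + record.S2)
    r = (record.S2 - record.S1) / record.interval
    return s_avg, r


def rate_model(S, fit: PETFit):
    """Annual signal change predicted at signal level S.

    r = (kappa/alpha)(S - b)(alpha - (S - b)); zero at S = b and S = b + alpha,
    maximal (kappa alpha / 4) at S = b + alpha/2.
    """
    S = np.asarray(S, dtype=float)
    x = S - fit.b
    out = (fit.kappa / fit.alpha) * x * (fit.alpha - x)
    return out if out.ndim else float(out)


def records_from_frame(df: pd.DataFrame) -> list:
    """Build PETRecords from a table with columns S1, S2, interval_years[, group]."""
    return [PETRecord(S1=row.S1, S2=row.S2, interval=row.interval_years,
                      group=getattr(row, "group", None))
            for row in df.itertuples()]


def fit_pet(records: Sequence[PETRecord], alpha_max: float = ALPHA_MAX,
            weights: Optional[np.ndarray] = None) -> PETFit:
    """Constrained least-squares fit of the rate-vs-signal parabola.

    Minimizes the squared error of predicted vs observed annual rates over
    (kappa, alpha, b), with alpha <= alpha_max and kappa, b > 0. Reports
    whether alpha finishes at its bound. ``weights`` (optional, per record)
    scale the residuals for heteroscedastic fits.
    """
    pairs = [annual_rate(rec) for rec in records]
    S = np.array([p[0] for p in pairs])
    r = np.array([p[1] for p in pairs])
    if len(records) < 3 or np.unique(S).size < 3:
        raise ValueError("need >= 3 records with distinct mean signals")
    w = np.ones_like(r) if weights is None else np.asarray(weights, float)

    degenerate = bool(np.allclose(r, 0.0))

    def resid(theta):
        kappa, alpha, b = theta
        x = S - b
        return w * ((kappa / alpha) * x * (alpha - x) - r)

    # initial guess from an unconstrained quadratic regression r ~ S:
    # r = -(kappa/alpha) S^2 + ..., vertex at b + alpha/2 with height
    # kappa alpha / 4
    c2, c1, _ = np.polyfit(S, r, 2)
    s_lo = float(S.min())
    if c2 < 0:
        s_vertex = -c1 / (2 * c2)
        r_vertex = max(float(np.polyval((c2, c1, _), s_vertex)), 1e-6)
        kappa0 = 2.0 * np.sqrt(r_vertex * (-c2))
        alpha0 = min(max(kappa0 / (-c2), 1e-3), alpha_max)
        b0 = max(s_vertex - alpha0 / 2.0, 1e-6)
        p0 = (kappa0, alpha0, b0)
    else:
        p0 = (0.1, min(alpha_max, max(1.0, S.max() - s_lo)), max(1e-3, 0.9 * s_lo))
    lb = [1e-8, 1e-6, 1e-8]
    ub = [np.inf, alpha_max, np.inf]
    res = least_squares(resid, np.clip(p0, lb, [1e6, alpha_max, 1e6]),
                        bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    kappa, alpha, b = res.x
    kappa = max(kappa, 1e-8)
    at_bound = bool(abs(alpha - alpha_max) < 1e-6)
    return PETFit(kappa=float(kappa), alpha=float(alpha), b=float(b),
                  residual=float(np.sum(res.fun**2)), alpha_at_bound=at_bound,
                  degenerate=degenerate, alpha_max=float(alpha_max))
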