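"""Exponential-phase replication-rate fit for transgenic-mouse seed data.

In P301S mice the seeding signal grows exponentially during early disease; a
straight-line fit in log space over the first months of life gives the
replication rate per month. To avoid region-availability bias, only time
points measured in every brain region enter the fit.

Because a published rate and its quoted doubling time can disagree depending
on whether the log-space slope was taken in natural log or log10, both
conventions are reported: ``kappa`` (natural-log slope, so the doubling time
is ln 2 / kappa) and ``slope_log10`` (decades per month, doubling time
log10(2) / slope_log10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MouseTimeCourse", "LogLinearFit", "filter_complete_timepoints",
           "fit_log_linear", "courses_from_frame"]


@dataclass
class MouseTimeCourse:
    """Seeding-signal time course for one brain region (times in months)."""

    region: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if (self.values <= 0).any():
            raise ValueError("seeding values must be positive")


@dataclass(frozen=True)
class LogLinearFit:
    """Exponential-phase fit: kappa is the natural-log slope per month."""

    kappa: float                 # /month, natural-log convention
    intercept_ln: float
    slope_log10: float           # decades/month
    n_points: int

    @property
    def doubling_time_months(self) -> float:
        return math.log(2.0) / self.kappa

    @property
    def doubling_time_months_log10_convention(self) -> float:
        """Doubling time if the quoted rate were a log10-space slope."""
        return math.log10(2.0) / self.slope_log10


def courses_from_frame(df: pd.DataFrame) -> list:
    """Build per-region time courses from columns region, time_months, value."""
    out = []
    for region, grp in df.groupby("region"):
        grp = grp.sort_values("time_months")
        agg = grp.groupby("time_months")["value"].apply(
            lambda v: float(np.exp(np.mean(np.log(v)))))
        out.append(MouseTimeCourse(region=str(region),
                                   times=agg.index.to_numpy(),
                                   values=agg.to_numpy()))
    return out


def filter_complete_timepoints(courses: Sequence[MouseTimeCourse]) -> np.ndarray:
    """Times at which every region was measured (bias-avoiding inclusion rule)."""
    if not courses:
        raise ValueError("need at least one time course")
    common = set(np.round(courses[0].times, 9))
    for c in courses[1:]:
        common &= set(np.round(c.times, 9))
    if not common:
        raise ValueError("no time point is present in all regions")
    return np.array(sorted(common))


def fit_log_linear(times, values, early_cutoff: float = 4.0) -> LogLinearFit:
    """OLS line through ln(value) vs time, restricted to t <= early_cutoff months.

    The slope is the replication rate kappa (per month, natural-log
    convention); the log10 slope is carried alongside for the alternative
    reading of published rates.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = times <= early_cutoff
    t, v = times[keep], values[keep]
    if t.size < 2:
        raise ValueError(
            f"need >= 2 time points at or before {early_cutoff} months, got {t.size}")
    slope, intercept = np.polyfit(t, np.log(v), 1)
    return LogLinearFit(kappa=float(slope), intercept_ln=float(intercept),
                        slope_log10=float(slope / math.log(10.0)),
                        n_points=int(t.size))


def fit_pooled(courses: Sequence[MouseTimeCourse], early_cutoff: float = 4.0,
               complete_only: bool = True) -> LogLinearFit:
    """Pooled exponential-phase fit over all regions.

    With ``complete_only`` (default) only times present in every region are
    used, matching the inclusion rule; values from all regions at the
    retained times are pooled into one log-linear regression.
    """
    if complete_only:
        keep_times = set(filter_complete_timepoints(courses))
        ts, vs = [], []
        for c in courses:
            sel = np.isin(np.round(c.times, 9), list(keep_times))
            ts.append(c.times[sel])
            vs.append(c.values[sel])
    else:
        ts = [c.times for c in courses]
        vs = [c.values for c in courses]
    return fit_log_linear(np.concatenate(ts), np.concatenate(vs), early_cutoff)
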