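"""Calibration of Braak stage against calendar time.

Braak staging orders postmortem tau pathology but carries no time axis. Under
the assumption that disease progression is similar across individuals and
that inter-individual variation comes mainly from the age of onset, the age
distribution of individuals observed at each stage is a shifted copy of a
common bell curve. Fitting per-stage Gaussians with a shared amplitude and SD
(determined by the early stages, where the curves are not cut off by the
100-year limit of the data) and stage-specific means turns mean-age
differences into per-stage durations — the "Braak clock" used to place
stage-resolved seed measurements on a common time axis.

Reference constants from the published 2332-individual staging survey are
shipped in :data:`TABLE_MEAN_AGES`, :data:`TABLE_CI` and
:data:`TABLE_DURATIONS`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "StageAgeTable",
    "GaussianStageModel",
    "conditional_stage_given_age",
    "fit_stage_gaussians",
    "stage_durations",
    "cumulative_stage_times",
    "collapse_substages",
    "principal_stage",
    "STAGES",
    "TABLE_MEAN_AGES",
    "TABLE_CI",
    "TABLE_DURATIONS",
    "BRAAK_CLOCK_FROM_III",
]

STAGES = ("0", "I", "II", "III", "IV", "V", "VI")

#: Published mean age (years) at each Braak stage from the Gaussian fits.
TABLE_MEAN_AGES = {"I": 51.0, "II": 70.0, "III": 84.0, "IV": 105.0, "V": 113.0, "VI": 118.0}

#: 95% confidence intervals on the mean ages.
TABLE_CI = {
    "I": (45.3, 57.1),
    "II": (65.7, 73.9),
    "III": (82.2, 86.2),
    "IV": (103.3, 106.5),
    "V": (108.4, 116.6),
    "VI": (115.3, 120.9),
}

#: Time to the next stage (years): consecutive differences of the mean ages.
TABLE_DURATIONS = {"I": 19.0, "II": 14.0, "III": 21.0, "IV": 8.0, "V": 5.0}

#: Years elapsed since the Braak III observation for stages III..VI —
#: partial sums of the stage durations; the time axis for stage-resolved data.
BRAAK_CLOCK_FROM_III = {"III": 0.0, "IV": 21.0, "V": 29.0, "VI": 34.0}

_ROMAN = re.compile(r"(VI|IV|V|III|II|I|0)")


def principal_stage(label: str) -> str:
    """Principal Braak stage of a substage label (first roman numeral found)."""
    m = _ROMAN.search(str(label).strip().upper())
    if not m:
        raise ValueError(f"cannot parse stage label {label!r}")
    return m.group(1)


@dataclass
class StageAgeTable:
    """Counts of individuals per age decade per Braak stage.

    ``counts`` is a DataFrame indexed by age-bin label (e.g. "61-70") with one
    column per stage; ``bin_centers`` maps each bin to its midpoint age.
    """

    counts: pd.DataFrame
    bin_centers: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.bin_centers is None:
            self.bin_centers = np.array([self._center(ix) for ix in self.counts.index])
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("age bins must be ordered and non-overlapping")

    @staticmethod
    def _center(label) -> float:
        nums = [float(x) for x in re.findall(r"\d+\.?\d*", str(label))]
        if len(nums) >= 2:
            return 0.5 * (nums[0] + nums[1])
        if len(nums) == 1:
            return nums[0]
        raise ValueError(f"cannot parse age-bin label {label!r}")

    @property
    def stages(self) -> list:
        return list(self.counts.columns)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @classmethod
    def from_csv(cls, path) -> "StageAgeTable":
        return cls(counts=pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.counts.to_csv(path)


def collapse_substages(table: StageAgeTable,
                       mapping: Optional[Mapping[str, str]] = None) -> StageAgeTable:
    """Collapse substage columns (e.g. "I/II") to the 7 groups 0, I..VI.

    Each substage maps to its principal stage by default; pass ``mapping`` to
    override. Stages below I stay pooled in group "0".
    """
    cols = {}
    for c in table.counts.columns:
        target = (mapping or {}).get(c, principal_stage(c))
        cols.setdefault(target, []).append(c)
    out = pd.DataFrame({s: table.counts[cs].sum(axis=1)
                        for s, cs in cols.items()}, index=table.counts.index)
    order = [s for s in STAGES if s in out.columns]
    extra = [s for s in out.columns if s not in order]
    return StageAgeTable(counts=out[order + extra], bin_centers=table.bin_centers)


@dataclass
class GaussianStageModel:
    """Shared-shape Gaussian model of per-stage age distributions.

    p_s(age) = amplitude * exp(-(age - means[s])² / (2 sigma²)) — one curve
    per stage with a common amplitude and SD; only the mean varies by stage.
    """

    amplitude: float
    sigma: float
    means: dict  # stage -> mean age (years)

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.amplitude <= 0:
            raise ValueError("amplitude and sigma must be positive")

    def curve(self, stage: str, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        return self.amplitude * np.exp(-0.5 * ((ages - self.means[stage]) / self.sigma) ** 2)

    def stage_probabilities(self, ages, stages: Sequence[str]) -> np.ndarray:
        """Row-normalized stage probabilities at each age (rows sum to 1)."""
        ages = np.asarray(ages, dtype=float)
        raw = np.column_stack([self.curve(s, ages) for s in stages])
        return raw / raw.sum(axis=1, keepdims=True)


def conditional_stage_given_age(table: StageAgeTable) -> pd.DataFrame:
    """P(stage | age bin): normalize each age row of the count table to sum to 1.

    Age bins with zero total count are dropped with a warning.
    """
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    if (totals == 0).all():
        raise ValueError("stage-age table has no counts")
    empty = totals == 0
    if empty.any():
        warnings.warn(f"dropping empty age bins: {list(counts.index[empty])}")
        counts = counts.loc[~empty]
        totals = totals[~empty]
    return counts.div(totals, axis=0)


def fit_stage_gaussians(
    prob_table: pd.DataFrame,
    bin_centers: Optional[np.ndarray] = None,
    early_stages: Sequence[str] = ("I", "II", "III"),
    late_stages: Sequence[str] = ("IV", "V", "VI"),
    age_cutoff: float = 100.0,
) -> GaussianStageModel:
    """Two-phase constrained Gaussian fit of the stage-given-age curves.

    Phase 1 fits the early-stage curves jointly with a shared amplitude and
    SD and free per-stage means. Phase 2 freezes the shared shape and fits
    only the mean of each late stage, evaluating the model solely on the
    observed bins (all at or below ``age_cutoff``), so the cut-off tail is
    handled by restriction and fitted means may exceed the cutoff.
    """
    for s in list(early_stages) + list(late_stages):
        if s not in prob_table.columns:
            raise ValueError(f"stage {s} missing from probability table")
    if bin_centers is None:
        bin_centers = np.array([StageAgeTable._center(ix) for ix in prob_table.index])
    ages = np.asarray(bin_centers, dtype=float)
    keep = ages <= age_cutoff
    ages_k = ages[keep]

    ne = len(early_stages)

    def early_model(a, amp, sigma, *means):
        cols = [amp * np.exp(-0.5 * ((a - m) / sigma) ** 2) for m in means]
        return np.concatenate(cols)

    y_early = np.concatenate([prob_table[s].to_numpy()[keep] for s in early_stages])
    m0 = [ages_k[np.argmax(prob_table[s].to_numpy()[keep])] for s in early_stages]
    p0 = [max(y_early.max(), 1e-3), 15.0, *m0]
    try:
        popt, _ = curve_fit(early_model, ages_k, y_early, p0=p0,
                            bounds=([1e-6, 1.0] + [0.0] * ne,
                                    [10.0, 100.0] + [200.0] * ne),
                            maxfev=20000)
    except RuntimeError as e:  # pragma: no cover - optimizer failure path
        raise RuntimeError(f"phase-1 Gaussian fit did not converge: {e}") from e
    amp, sigma = popt[0], popt[1]
    means = dict(zip(early_stages, popt[2:]))

    for s in late_stages:
        y = prob_table[s].to_numpy()[keep]

        def late_model(a, m):
            return amp * np.exp(-0.5 * ((a - m) / sigma) ** 2)

        m_init = max(ages_k[np.argmax(y)], means[early_stages[-1]] + 5.0)
        try:
            popt_s, _ = curve_fit(late_model, ages_k, y, p0=[m_init],
                                  bounds=(0.0, 400.0), maxfev=20000)
        except RuntimeError as e:  # pragma: no cover
            raise RuntimeError(
                f"phase-2 Gaussian fit did not converge for stage {s}: {e}") from e
        means[s] = float(popt_s[0])

    model = GaussianStageModel(amplitude=float(amp), sigma=float(sigma),
                               means={s: float(means[s])
                                      for s in list(early_stages) + list(late_stages)})
    return model


def stage_durations(model_or_means) -> dict:
    """Per-stage durations (years): consecutive differences of mean ages.

    Accepts a :class:`GaussianStageModel` or a mapping stage -> mean age.
    Returns {stage: time to the next stage}.
    """
    means = (model_or_means.means if isinstance(model_or_means, GaussianStageModel)
             else dict(model_or_means))
    stages = [s for s in STAGES if s in means]
    vals = [means[s] for s in stages]
    diffs = np.diff(vals)
    if (diffs <= 0).any():
        raise ValueError(f"mean ages must increase with stage, got {means}")
    return {s: float(d) for s, d in zip(stages[:-1], diffs)}


def cumulative_stage_times(model_or_means, anchor: str = "III") -> dict:
    """Years elapsed at each stage relative to the anchor stage's mean age."""
    means = (model_or_means.means if isinstance(model_or_means, GaussianStageModel)
             else dict(model_or_means))
    if anchor not in means:
        raise ValueError(f"anchor stage {anchor!r} not in means")
    stage_durations(means)  # validates monotonicity
    t0 = means[anchor]
    return {s: float(means[s] - t0) for s in means if means[s] >= t0}
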