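"""Seedable generators emulating every study input.

Five generators mirror the five kinds of data the analysis consumes:

* region-resolved seed titers across Braak stages (logistic growth in time,
  multiplicative lognormal noise, geometric initial-fraction gradient away
  from the entorhinal cortex);
* stage-by-age count tables (shared-shape Gaussian stage-age structure,
  multinomial sampling, ages truncated at 100 years);
* longitudinal PET visit pairs (logistic-rate locus with additive rate noise);
* mouse seed time courses (early exponential growth, lognormal noise, an
  availability pattern of missing late time points per region);
* two-color synthetic brightfield slides (hematoxylin-like nuclei disks and
  DAB-like tau blobs whose colors are verified against the quantification
  windows at generation time, with painted-pixel ground truth).

Every generator is a pure function of its :class:`GeneratorSpec`: the same
seed and scenario produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import histology
from .braak import BRAAK_CLOCK_FROM_III, GaussianStageModel, StageAgeTable
from .core import logistic_fraction
from .fkpp import REGION_LABELS
from .inference import MeasurementSet
from .mouse import MouseTimeCourse
from .pet import PETRecord

__all__ = [
    "GeneratorSpec",
    "SCENARIOS",
    "gen_seed_dataset",
    "gen_stage_age_table",
    "gen_pet_cohort",
    "gen_mouse_timecourses",
    "gen_histology_image",
]

#: Named parameter bundles. The *-like scenarios encode the study designs:
#: "devos-like" — six regions, subject counts 7/4/6/2 at Braak III-VI on the
#: Braak-clock time axis; "pet-like" — 101 visit pairs ~2 years apart with the
#: published fit (kappa 0.17 /yr, alpha 4, b 1.06) as truth; "mouse-like" —
#: three regions growing at 0.6 /month; "braak-like" — 2332 individuals,
#: 10 age decades, stage means from the published Gaussian fits.
SCENARIOS: dict = {
    "devos-like": dict(
        kappa=0.17,                      # /yr
        alpha=100.0,                     # assay units at plateau
        f0_ec=1e-3,                      # initial fraction in the EC
        f0_decay=0.3,                    # geometric decay per region step
        sigma_log10=0.5,                 # replicate scatter, log10 units
        subjects_per_stage={"III": 7, "IV": 4, "V": 6, "VI": 2},
        stage_times=dict(BRAAK_CLOCK_FROM_III),
        regions=list(REGION_LABELS),
        replicates=2,                    # repeat measurements per subject/region
    ),
    "pet-like": dict(
        kappa=0.17, alpha=4.0, b=1.06, n=101, interval=2.0,
        rate_noise_sd=0.01,              # SUVr / yr
        span=0.8,                        # S1 sampled on [b, b + span * alpha]
    ),
    "mouse-like": dict(
        kappa=0.6,                       # /month
        regions={"brainstem": 1.0, "neocortex": 0.5, "frontal lobe": 0.3},
        times=[1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0],
        missing={"neocortex": [5.0], "frontal lobe": [6.0]},
        sigma_ln=0.3,
    ),
    "braak-like": dict(
        n=2332,
        amplitude=0.3, sigma=15.0,
        means={"I": 51.0, "II": 70.0, "III": 84.0,
               "IV": 105.0, "V": 113.0, "VI": 118.0},
        age_weights=[0.01, 0.01, 0.02, 0.04, 0.08, 0.12, 0.17, 0.23, 0.20, 0.12],
    ),
    "ihc-like": dict(
        shape=(384, 384), n_cells=50, n_tau=3,
        cell_radius=12, tau_radius=18,
        cell_hsb=(150.0, 80.0, 190.0),   # hematoxylin-like blue-purple
        tau_hsb=(25.0, 120.0, 150.0),    # DAB-like brown
        background_hsb=(0.0, 0.0, 250.0),
        margin=6,
    ),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Seeded, named generator configuration; overrides patch the scenario."""

    seed: int
    scenario: str
    overrides: dict = field(default_factory=dict)

    def params(self) -> dict:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"known: {sorted(SCENARIOS)}")
        p = {k: (dict(v) if isinstance(v, dict) else v)
             for k, v in SCENARIOS[self.scenario].items()}
        for k, v in self.overrides.items():
            if k not in p:
                raise ValueError(f"unknown parameter {k!r} for scenario "
                                 f"{self.scenario!r}")
            p[k] = v
        return p

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_seed_dataset(spec: GeneratorSpec) -> MeasurementSet:
    """Region-resolved seed titers across Braak stages.

    Per subject, region and replicate, the value is the logistic signal at
    the stage's Braak-clock time, with a region-specific initial fraction
    decaying geometrically with distance from the EC, times lognormal noise.
    """
    p = spec.params()
    rng = spec.rng()
    counts = p["subjects_per_stage"]
    if any(int(c) < 1 for c in counts.values()):
        raise ValueError("subject counts must be >= 1 per stage")
    f0s = {r: p["f0_ec"] * p["f0_decay"] ** i for i, r in enumerate(p["regions"])}
    rows = []
    sid = 0
    for stage, n_subj in counts.items():
        t = p["stage_times"][stage]
        for _ in range(int(n_subj)):
            sid += 1
            for region in p["regions"]:
                mean_log = np.log10(
                    p["alpha"] * logistic_fraction(t, p["kappa"], f0s[region]))
                for rep in range(int(p["replicates"])):
                    noise = rng.normal(0.0, p["sigma_log10"]) if p["sigma_log10"] > 0 else 0.0
                    rows.append({
                        "subject": f"S{sid:03d}",
                        "region": region,
                        "stage": stage,
                        "time_years": t,
                        "value": 10.0 ** (mean_log + noise),
                        "assay": "seed_amplification",
                        "replicate": rep,
                    })
    return MeasurementSet(pd.DataFrame(rows))


def gen_stage_age_table(spec: GeneratorSpec) -> StageAgeTable:
    """Stage-by-age decade counts from a shared-shape Gaussian stage model.

    For each age decade (1-10 ... 91-100; truncation at 100 years is built
    into the binning), individuals are assigned multinomially to stages with
    probabilities proportional to the per-stage Gaussian curves evaluated at
    the bin center; the remainder is the pooled below-stage-I group "0".
    """
    p = spec.params()
    rng = spec.rng()
    model = GaussianStageModel(amplitude=p["amplitude"], sigma=p["sigma"],
                               means=dict(p["means"]))
    edges = [(10 * i + 1, 10 * (i + 1)) for i in range(10)]
    labels = [f"{a}-{b}" for a, b in edges]
    centers = np.array([(a + b) / 2.0 for a, b in edges])
    stages = list(p["means"])
    weights = np.asarray(p["age_weights"], float)
    weights = weights / weights.sum()
    n_per_bin = rng.multinomial(int(p["n"]), weights)

    table = np.zeros((10, len(stages) + 1), dtype=int)
    for i, (c, n_bin) in enumerate(zip(centers, n_per_bin)):
        probs = np.array([model.curve(s, c) for s in stages])
        total = probs.sum()
        if total > 1.0:  # defensive: scenario amplitudes keep this below 1
            probs = probs / total
            total = 1.0
        full = np.concatenate([[1.0 - total], probs])
        table[i] = rng.multinomial(int(n_bin), full)
    counts = pd.DataFrame(table, index=labels, columns=["0"] + stages)
    return StageAgeTable(counts=counts, bin_centers=centers)


def gen_pet_cohort(spec: GeneratorSpec) -> list:
    """Longitudinal PET visit pairs on the logistic rate-vs-signal locus.

    First-visit signals are uniform on [b, b + span * alpha]; the annual rate
    is the differentiated logistic plus Gaussian noise, and the second visit
    is constructed so that the annualized difference recovers that rate.
    """
    p = spec.params()
    rng = spec.rng()
    records = []
    for _ in range(int(p["n"])):
        s1 = rng.uniform(p["b"], p["b"] + p["span"] * p["alpha"])
        x = s1 - p["b"]
        r_true = (p["kappa"] / p["alpha"]) * x * (p["alpha"] - x)
        r = r_true + (rng.normal(0.0, p["rate_noise_sd"])
                      if p["rate_noise_sd"] > 0 else 0.0)
        interval = p["interval"]
        records.append(PETRecord(S1=float(s1), S2=float(s1 + r * interval),
                                 interval=float(interval)))
    return records


def gen_mouse_timecourses(spec: GeneratorSpec) -> list:
    """Per-region exponential seed growth with configurable missing times."""
    p = spec.params()
    rng = spec.rng()
    courses = []
    for region, v0 in p["regions"].items():
        drop = set(p["missing"].get(region, []))
        times = np.array([t for t in p["times"] if t not in drop], float)
        mean = v0 * np.exp(p["kappa"] * times)
        noise = (np.exp(rng.normal(0.0, p["sigma_ln"], size=times.size))
                 if p["sigma_ln"] > 0 else np.ones_like(times))
        courses.append(MouseTimeCourse(region=region, times=times,
                                       values=mean * noise))
    return courses


def _place_disks(rng, shape, n, radius, margin, occupied_centers):
    """Rejection-sample n non-touching disk centers with the given margin."""
    h, w = shape
    centers = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place disks without overlap; "
                               "reduce counts or radii")
        c = (rng.integers(radius + margin, h - radius - margin),
             rng.integers(radius + margin, w - radius - margin))
        ok = all((c[0] - o[0]) ** 2 + (c[1] - o[1]) ** 2
                 >= (radius + orad + margin) ** 2
                 for o, orad in occupied_centers + [(cc, radius) for cc in centers])
        if ok:
            centers.append(c)
    return centers


def gen_histology_image(spec: GeneratorSpec) -> tuple:
    """Synthetic two-color brightfield slide plus painted ground truth.

    Paints a near-white background, ``n_cells`` nucleus disks in a
    hematoxylin-like color and ``n_tau`` tau blobs in a DAB-like color. Each
    color is converted RGB->HSB and checked against the module's windows at
    generation time: the nucleus color must pass only the cell window, the
    tau color only the tau window, the background neither — otherwise the
    generator raises. Returns ``(image, truth)`` where ``truth`` records the
    disk centers, the nucleus count and the exact painted tau pixel area.
    """
    p = spec.params()
    rng = spec.rng()
    shape = tuple(p["shape"])

    colors = {}
    for name, hsb in (("cell", p["cell_hsb"]), ("tau", p["tau_hsb"]),
                      ("background", p["background_hsb"])):
        rgb = histology.rgb_from_hsb255(*hsb)
        pixel = np.array(rgb, dtype=np.uint8).reshape(1, 1, 3)
        in_cell = bool(histology.hsb_threshold(pixel, histology.CELL_WINDOW)[0, 0])
        in_tau = bool(histology.hsb_threshold(pixel, histology.TAU_WINDOW)[0, 0])
        expected = {"cell": (True, False), "tau": (False, True),
                    "background": (False, False)}[name]
        if (in_cell, in_tau) != expected:
            raise ValueError(
                f"{name} color HSB={hsb} fails window validation: "
                f"in_cell={in_cell}, in_tau={in_tau}, expected {expected}")
        colors[name] = rgb

    img = np.empty(shape + (3,), dtype=np.uint8)
    img[...] = colors["background"]

    rc, rt = int(p["cell_radius"]), int(p["tau_radius"])
    margin = int(p["margin"])
    tau_centers = _place_disks(rng, shape, int(p["n_tau"]), rt, margin, [])
    occupied = [(c, rt) for c in tau_centers]
    cell_centers = _place_disks(rng, shape, int(p["n_cells"]), rc, margin, occupied)

    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    tau_mask = np.zeros(shape, bool)
    for (cy, cx) in tau_centers:
        tau_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rt**2
    cell_mask = np.zeros(shape, bool)
    for (cy, cx) in cell_centers:
        cell_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rc**2
    img[tau_mask] = colors["tau"]
    img[cell_mask] = colors["cell"]

    truth = {
        "n_cells": int(p["n_cells"]),
        "n_tau": int(p["n_tau"]),
        "cell_centers": cell_centers,
        "tau_centers": tau_centers,
        "tau_area_px": int(tau_mask.sum()),
        "cell_area_px": int(cell_mask.sum()),
    }
    return img, truth
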