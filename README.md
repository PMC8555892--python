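# taukinetics

Chemical kinetics of tau seed accumulation in Alzheimer's disease.

In AD, replication-competent tau aggregates ("seeds") both multiply locally
and spread between brain regions. Which of the two processes limits the
overall rate of accumulation decides where a therapy should aim. This
package implements the kinetic analysis that answers that question from
region- and time-resolved measurements of tau seeds and aggregates: it is
written for quantitative neuroscientists and biophysicists who want to fit
effective replication and spreading rates to seed-amplification, IHC, ELISA,
tangle-count or longitudinal tau-PET data — or to synthetic emulations of
those study designs.

## The model

Seed load relative to its local maximum, f(**r**, t) ∈ [0, 1], follows the
Fisher–KPP reaction-diffusion equation

    ∂f/∂t = D ∇²f + κ f (1 − f)

with effective diffusion coefficient D (spreading) and effective replication
rate κ. Two limits emerge: *spreading-limited* kinetics (a sharp front
crosses the tissue; the time scale is set by the geometric mean √(Dκ), front
speed 2√(Dκ)) and *replication-limited* kinetics (seeds are everywhere
before any region saturates; the time scale is set by κ alone). For a
compact seed source the switch occurs near D/κ ≈ 0.0025 r²_max.

In the replication limit the signal measured by an assay with scale α and
baseline b is the logistic

    S(t) = α f₀ e^{κt} / (1 − f₀ + f₀ e^{κt}) + b,

whose differentiated form r = (κ/α)(S − b)(α − (S − b)) links the annualized
rate of PET signal change to the signal itself. The replication rate further
decomposes into growth and multiplication rates through the mean aggregate
size μ (monomers): κ = √(k_growth · k_mult), μ = √(k_growth / k_mult).

Module map: `core` (closed-form kinetics and unit conversions), `fkpp`
(numerical solver, regime classification, regional fit, intervention
comparison), `braak` (Braak-stage-to-time calibration from stage-by-age
tables), `inference` (grid-Bayesian κ estimation and posterior combination),
`pet` (longitudinal PET rate fits), `mouse` (exponential-phase mouse fits),
`histology` (AT8 IHC quantification), `synthetic` (seedable generators for
all five input kinds), `cli` (command-line pipeline).

## Worked example

Generate a synthetic postmortem seed-amplification cohort (six regions EC,
H, PHG, AC, VA, PV; 7/4/6/2 subjects at Braak stages III–VI placed at 0, 21,
29 and 34 years on the Braak clock; true κ = 0.17 /yr) and infer the
replication rate:

```bash
taukinetics generate --scenario devos-like --seed 3 --out seed.csv
taukinetics infer-kappa --measurements seed.csv --out kappa.json
```

```
kappa = 0.171 +/- 0.006 /yr
```

The posterior mean recovers the generating rate within one standard
deviation; `kappa.json` also reports the 95% credible interval
(0.156–0.180 /yr) and the implied doubling time ln 2/κ ≈ 4.0 years. The
full pipeline

```bash
taukinetics run-all --outdir out --seed 0
```

prints `combined kappa = 0.165 /yr (doubling time 4.20 yr)` and writes
`out/summary.json` containing, for the same seed: the Braak-clock stage
durations fitted from a synthetic 2332-individual stage-age table (means
within ~3 yr of the generating values 51/70/84/105/113/118), the regional
reaction-diffusion fit and the factor-3 intervention comparison (slowing
replication delays half-maximal seed load by ~228 yr versus ~3 yr for
slowing spreading — the hallmark of replication-limited kinetics), the PET
rate fit (κ ≈ 0.169 /yr, α at its 4-SUVr bound, b ≈ 1.13), the mouse
exponential fit (κ ≈ 0.53 /month), and the growth/multiplication
decomposition at μ = 750 monomers (k_growth ≈ 124 /yr,
k_mult ≈ 2.2 × 10⁻⁴ /yr).

As a pure library:

```python
from taukinetics import core
core.doubling_time(0.14)            # 4.95 years
core.fibril_monomer_count(176.0)    # 749 monomers in a 176-nm fibril
core.decompose_rates(0.14, 750.0)   # k_growth=105 /yr, k_mult=1.87e-4 /yr
```

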