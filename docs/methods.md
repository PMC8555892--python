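# Methods

This note records the models implemented in `taukinetics`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the limitations a user should keep in mind.

## Reaction-diffusion model and numerics

The central object is the Fisher–KPP equation ∂f/∂t = D∇²f + κf(1−f) for the
relative seed load f ∈ [0, 1] on a 1-D interval or on a chain of equally
spaced brain regions (EC, H, PHG, AC, VA, PV, ordered by synaptic distance
from the entorhinal cortex). Zero-flux (Neumann) boundaries are used: the
brain is a closed volume for seeds, and pure diffusion then conserves total
seed mass exactly — a property the test suite asserts to 1e-6.

Time stepping is operator-split per step: diffusion is advanced with
Crank–Nicolson (tridiagonal solve; unconditionally stable, second-order,
mass-conserving), and the logistic reaction with its pointwise *exact*
solution f → f e^{κΔt}/(1 − f + f e^{κΔt}) rather than an explicit Euler
update. Two consequences drive this choice: spatially uniform fields follow
the closed-form logistic curve to machine precision regardless of the step,
and no reaction-stability constraint exists. A step-size guard still rejects
user-supplied steps above 0.5/κ, the point beyond which splitting error
degrades accuracy noticeably. Defaults: 201 grid points on the interval,
internal step 0.05/κ. Halving both grid and step changes final profiles by
< 1e-3 (sup-norm), and the measured speed of the f = 0.5 level set matches
the pulled-front prediction 2√(Dκ) within 10% once the slow ~1/t velocity
transient has decayed — the validation tracks the interpolated front over
the second half of a 4-length-unit domain for this reason.

**Regime classification.** At the first stored time when the spatial mean of
f crosses 1/2, the heterogeneity index χ is the fraction of grid points
still below `low` = 0.05. χ > 0.25 labels the trajectory spreading-limited
(a front with a seed-free tail), χ < 0.05 replication-limited (near-uniform
growth), otherwise intermediate. The thresholds are configuration values
chosen so that, for a compact Gaussian bump of width 0.01·r_max, the label
switches within a factor of 3 of the analytic boundary D/κ = 0.0025 r²_max,
and so that the reference pairs D/κ = 0.00025 and 0.025 (unit length)²
classify as spreading- and replication-limited respectively.

**Regional fit.** Stage-resolved regional signal profiles are fitted on the
6-node chain with κ held fixed (default 0.14 /yr, the cross-dataset
combined estimate). Free parameters: D, the signal ceiling P_max, and the
clock offset t_start ∈ [t(III), t(VI)] at which the dynamics start; the
Braak-III profile divided by P_max is the initial condition, and stages
observed before t_start keep that profile. The loss is the sum of squared
residuals of log10 signal over the later stages — seed titers span several
orders of magnitude, so a linear-space loss would fit only the largest
values. Optimization is Nelder–Mead from four starts in (log10 D,
log10 P_max, t_start) with parameters clipped to the search box; a
parameter finishing at a bound is recorded as a warning in the fit.
Within the fit the simulator runs at a coarser internal step (0.25/κ);
the reaction substep being exact, this changes recovered parameters by
well under the 5% recovery tolerance while keeping an objective
evaluation near a millisecond.

**Intervention comparison.** The fitted configuration is re-simulated with
D/factor and separately κ/factor (default factor 3) and the increase in the
time for the spatial-mean seed load to reach half of P_max is reported. A
horizon-censored delay is returned as NaN rather than a fabricated number.

## Braak clock

Stage-by-age count tables (10 age decades spanning 1–100 years) are
row-normalized to P(stage | age). Each stage's curve is modelled as a
Gaussian with a *shared* amplitude and SD and a stage-specific mean — the
operational form of the assumption that disease progression is similar
across individuals and only onset age varies. Phase 1 fits stages I–III
jointly (shared shape determined where the curves are fully observable);
phase 2 freezes the shape and fits only the means of IV–VI. Truncation at
100 years is handled by evaluating the model only on observed bins, so
fitted late-stage means may exceed 100 years (the reference values are
105/113/118). The objective is unweighted least squares on the probability
curves, not a count likelihood: the calibration target is the curve shape,
and bins with few individuals would otherwise dominate through their
multinomial variance in ways the shared-shape model is not meant to absorb.
Consecutive differences of mean ages give per-stage durations; anchored at
stage III the cumulative clock is 0/21/29/34 years for III/IV/V/VI, the time
axis used for all stage-resolved datasets. Substage labels (e.g. "I/II")
collapse to their principal stage by default; the mapping is overridable
because the original 12-substage binning is not fully specified.

## Replication-rate inference

Measurements are modelled as log10 S(t) = log10[α f(t; κ, f₀)] + ε,
ε ~ N(0, σ²), with σ fixed from the pooled within-replicate SD of log10
values. The Gaussian-on-log-signal choice reflects how such assay data are
displayed and averaged (multiplicative, order-of-magnitude scatter); a
linear-space likelihood can be selected by transforming inputs upstream.
The posterior over (κ, f₀, α) is evaluated on a dense grid — κ and f₀
log-spaced with 1/x priors (uniform mass per node), α linear with a flat
prior between the largest observed value and 100× it, f₀ bounded to
[1e-10, 0.01] (one seed per brain up to 1% of the final concentration).
Grid resolution: 240 κ points on [1e-3, 10] /yr, 80 f₀ points, 60 α points.
The κ axis is finer than the f₀/α axes because posteriors combined across
six regions shrink by √6; at half this resolution the grid spacing near
κ ≈ 0.17 /yr exceeds the combined posterior SD and credible intervals
become erratically sized. More than 1% of posterior mass on the κ/f₀ grid
boundary is flagged in the result metadata.

Regions are analyzed separately (each with its own f₀ and α), marginalized
to 1-D κ posteriors, and combined by pointwise product on a common grid;
datasets are combined the same way with equal weight, an assumption recorded
as such since the original weighting across differently sized experiments is
not specified. Likelihood evaluation factors the α dependence analytically
(per-(κ, f₀) sufficient statistics), so a full grid costs milliseconds. A
least-squares fit to per-time medians is provided for display parity; it
shares κ with the Bayesian estimate but its f₀ and α trade off strongly
when all observations sit in the exponential phase.

Calibration: across replicated synthetic cohorts of the six-region design
(7/4/6/2 subjects at 0/21/29/34 yr, σ_log10 = 0.5), the mean ± 1 SD interval
of the combined posterior contains the generating κ in ~75% of runs —
consistent with Gaussian-like 68% coverage given plug-in σ.

## PET rate fit

Visit pairs (S₁, S₂, Δt ≈ 2 yr) give S_avg = (S₁+S₂)/2 and r = (S₂−S₁)/Δt.
The fit minimizes squared rate residuals of r = (κ/α)(S−b)(α−(S−b)) under
α ≤ 4 SUVr (a conservative plateau bound), κ, b > 0. The initial guess is
derived from an unconstrained quadratic regression of r on S (curvature →
κ/α, vertex → b + α/2 and κα/4), which removes the optimizer's dependence on
a hand-picked start. Whether α finishes at its bound is reported; relaxing
the bound can only reduce the residual, and the tests assert exactly that.
Residuals are unweighted by default; per-record weights are accepted for
heteroscedastic designs. All records enter the fit regardless of diagnostic
group unless the caller filters them.

## Mouse fit

Seeding signals in transgenic mice grow exponentially in early disease; an
OLS line through ln(value) versus time restricted to t ≤ 4 months gives κ
per month. Only time points measured in every brain region are used, the
inclusion rule that avoids availability bias. Because a quoted rate of this
kind is ambiguous between natural-log and log10 slope conventions — the two
imply doubling times of ln 2/κ versus log10(2)/κ′, a factor-2.3 difference —
both slopes and both implied doubling times are always reported side by
side, and neither is promoted as canonical.

## Histology quantification

Nuclei: HSB window (hue 108–200, saturation 25–141, brightness 145–230 on
the 0–255 scale) → one 3×3 dilation → hole filling → watershed on the
negated Euclidean distance transform seeded by h-maxima (depth 1 px) →
particles kept if area ≥ 200 px² and circularity 4πA/P² > 0.5, with the
perimeter taken from 8-connected boundary tracing. Tau: HSB window hue ≤ 44
or ≥ 222 (a wrapping window — brown DAB hues straddle the hue origin, and a
conjunctive reading would be empty), saturation ≥ 42, brightness ≤ 206; the
passing pixel count is the tau area, and burden = tau area / nucleus count
(undefined, not zero, when no nuclei are found). The area/circularity filter
is applied after the watershed split, matching the order of the classical
particle-analysis pipeline. On synthetic slides the nucleus count is
recovered exactly and the painted tau area within 2%.

## Synthetic-data generators

Each generator is a pure function of (seed, scenario, overrides) and its
outputs are bit-identical across reruns. Scenario defaults encode the study
designs: `devos-like` (6 regions, 7/4/6/2 subjects at Braak III–VI on the
0/21/29/34-yr clock, κ = 0.17 /yr, plateau signal α = 100, two replicates
per subject/region); `pet-like` (101 visit pairs ~2 yr apart, truth
κ = 0.17 /yr, α = 4, b = 1.06, baseline signals uniform over the lower 80%
of the sigmoid span, rate noise SD 0.01 SUVr/yr); `braak-like` (2332
individuals over 10 age decades, stage means 51/70/84/105/113/118 yr,
shared σ = 15 yr, amplitude 0.3, an age distribution weighted toward the
later decades as in autopsy series, truncation at 100 yr built into the
binning); `mouse-like` (three regions, κ = 0.6 /month, lognormal noise
σ_ln = 0.3, region-specific missing late time points); `ihc-like`
(384×384 px, 50 nuclei of radius 12 px, 3 tau blobs of radius 18 px,
colors validated against the quantification windows at generation time).

Choices not fixed by any published number, made once: seed-data noise
σ_log10 = 0.5 (order-of-magnitude scatter typical of seed-amplification
replicates); initial-fraction gradient f₀(region) = 10⁻³ · 0.3^i with i the
chain distance from the EC (a qualitative early-stage gradient, not a copy
of any subject-level data); the stage-age amplitude 0.3 keeps the six stage
curves summing below 1 at every observable age so the below-stage-I pool is
their exact complement.

What the generators do **not** emulate: inter-subject onset-age variability
within a stage (subjects at a stage share the stage's clock time), brain
connectome structure (the chain is the model's own geometry, so regional-fit
recovery tests validate the fitting machinery, not anatomical realism),
assay-specific saturation or floor artifacts, PET partial-volume effects,
and staining variability beyond two uniform colors. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated noise
models, not robustness to real-data systematics.

## Problem sizes and tolerances

The suite uses the study-scale designs where the criterion names them (20
DeVos-like replicate cohorts, 101-record PET cohorts, 2332-individual
stage-age tables) and 12 replicate cohorts for the Braak-clock
median-error check; the 40-cohort coverage check is the package's own
compromise between Monte-Carlo error (±8% at 40 runs) and runtime. Front
speed is validated on a 1201-point grid. Numerical tie-breaks: posterior
mass exactly on a grid node stays there under marginalization; watershed
over-segmentation is suppressed before marker labelling rather than by
post-merging; the regional fit reports rather than silently clamps
at-bound parameters.

## Known limitations

Diffusion constants from the 6-node chain are order-of-magnitude estimates
only; the paper-scale conversion (r_max = 10 cm, year = 3.15576e7 s) is
exposed in `core` but no anatomical geometry is attempted. The Bayesian
machinery assumes independent noise across measurements; subject-level
random effects are deliberately out of scope. The equal-weight product
combining datasets makes large datasets dominate through their likelihoods
alone. Fitted Braak means beyond ~120 years extrapolate a Gaussian far past
the data and inherit its shape assumption; their confidence comes from the
shared-SD constraint, not from observations at those ages.
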