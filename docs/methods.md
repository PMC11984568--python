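# Methods

`cbctplan` is a desk-scale computational model of CBCT-based online-adaptive
intensity-modulated proton therapy (IMPT) planning for head-and-neck targets.
It reproduces, on seeded synthetic phantoms, the computational chain of a
robust-planning study: scenario-based mini-max robust spot-weight
optimization with configurable setup (SRS) and range (RRS) robustness
settings, and a ground-truth evaluation chain built on the voxel-wise
minimum (VoxMin) dose composite, CT-number error statistics, logistic NTCP
models, population percentiles and paired signed-rank testing.  Nothing in
the package depends on patient data; every input is generated by the
`phantoms` module.

## Synthetic anatomy

A phantom is a 2-D axial-slice analogue on a regular voxel grid (default
128 x 128 at 2 mm; all grid types also accept 3-D arrays).  The noise-free
image is piecewise constant: soft tissue (+30 HU) inside an elliptical body,
a bone shell near the body surface plus a vertebra-like disk (+700 HU), an
anterior air cavity (-1000 HU).  Structures are binary masks: nested
clinical target volumes (`ctv_high`, 70 Gy analogue, inside `ctv_low`,
54.25 Gy analogue), two organ-at-risk analogues (a parotid-like and a
constrictor-like ellipse, both abutting but excluded from the elective
target so their dose is penumbra- and margin-driven), and an optional metal
avoidance disk.  Per-phantom geometry jitter is drawn from a seeded
generator; all generators are bit-reproducible for a fixed seed.

The default geometry is 2-D because the mechanisms under study — range
errors from CT-number errors, setup shifts, margin expansion — are fully
expressible in one axial plane at a fraction of the 3-D cost.  One known
consequence: the "1-D range expansion vs 3-D setup expansion" asymmetry that
favours range robustness over setup robustness in 3-D is compressed to
1-D-vs-2-D here, so organ-at-risk differences between the online (1 mm SRS)
and offline (3 mm SRS) arms are smaller than a 3-D model would show.

## CBCT error field

`generate_cbct` corrupts the ground-truth image with four components whose
population statistics are the study's stated conditions:

* a per-phantom global CT-number offset, N(15, 20) HU — CBCT numbers tend to
  be globally elevated;
* a spatially correlated zero-mean field, 100 HU sd inside the body with a
  25 mm Gaussian correlation length — the long-range scatter/cupping-like
  shading that dominates CBCT inaccuracy.  The correlation length matters
  more than the amplitude: a short-correlation field of equal MAE averages
  out along ray paths and produces almost no water-equivalent range error,
  which would decouple image error from dosimetric error entirely;
* boosted errors in a band around bone/air interfaces (dilated boundary,
  radius 2 voxels; amplitude 240 HU with a +25% positive bias), emulating
  the interface artifacts where CBCT errors concentrate;
* a small rigid intra-fraction motion residue (0.7 mm sd per axis) applied
  before differencing, producing large local errors at tissue boundaries.

With these defaults a default-geometry cohort reproduces a population-mean
MAE of ~145 HU and mean error of ~22 HU inside the body (air cavities below
-960 HU excluded, judged on the reference image), the calibration targets
the study design prescribes.  The per-phantom spread of the mean error
(~±75 HU) is larger than the ±45 HU a clinical CBCT cohort shows; this is
the price of driving most of the error through the long-range field, and it
is the main respect in which the synthetic error model is coarser than real
data.  No projection-domain physics (scatter, beam hardening,
reconstruction) is simulated.

Typical induced water-equivalent range errors at the target are 2–15%
(median ≈ 7%) of the nominal ~100 mm depth — large enough that a 3% range
robustness setting cannot absorb them for error-heavy phantoms, and small
enough that 10–12% usually can.  That window is what makes the
range-robustness sweep informative.

## Planning anatomy (offline reference)

The earlier "planning-CT" anatomy is derived from the ground truth by
rigidly shifting the targets (magnitude |N(2.5, 1.2)| mm clipped at 6 mm,
random direction) and rescaling them isotropically (factor N(1, 0.04))
about the elective target's centroid, clipped to the body and away from air.
The HU image is unchanged — the targets are soft-tissue-isodense, so target
drift is invisible in HU, which is precisely why offline planning needs the
larger setup margin.  The magnitude is a synthetic choice (the clinical
inter-fraction drift distribution is not part of the model) set so that a
3 mm setup margin protects most, but not all, phantoms.

## Dose engine

CT numbers convert to relative stopping power (RSP) through a
piecewise-linear calibration curve (default nodes (-1024, 0.001), (0, 1.0),
(1000, 1.55), (3071, 2.4), anchored at water); values clamp at the end
nodes.  Beams are parallel (no source divergence) at the six standard
gantry angles (50, 100, 160, 200, 260, 310 degrees).  Water-equivalent path
length (WEPL) is traced per beam on a (lateral x depth) ray grid at 1 mm
steps with bilinear RSP lookup, then interpolated to voxel centres.

The depth-dose curve is an analytic stand-in for a measured Bragg curve: a
Gaussian peak at the nominal range (width min(3 mm, 0.06 x range)) on top
of a smooth entrance plateau (relative height 0.3) that switches off 10 mm
proximal to the peak.  It is normalized to 1.0 at the peak, peaks exactly
at the nominal range, and falls below 1% of the peak by 1.2 x the range.
The lateral profile is a fixed-width Gaussian (sigma 4 mm).  Nuclear halo,
Monte Carlo transport and depth-dependent lateral scattering are out of
scope; the engine preserves the two mechanisms the study turns on — range
scaling and setup shifts — and nothing else.

Spot lattices are target-conformal: lateral positions tile the elective
target's lateral extent (5 mm spacing, 6 mm margin), and per lateral
position nominal ranges tile the WEPL interval of nearby target voxels
(5 mm spacing, 3 mm margin).  Two widenings matter in practice: the range
interval is expanded by the fractional density scaling the plan will be
optimized with (range-error scenarios need peaks outside the nominal
extent), and the lateral neighbourhood defining each range interval is
widened by the setup robustness setting (a laterally shifted voxel may sit
behind very different upstream material, e.g. an air cavity).  Within a
study, one lattice per planning image is built, wide enough for the largest
RRS in the sweep, so the sweep varies only the scenario set, not the
delivery system.  Spots whose central ray crosses an avoidance structure
proximal to the Bragg peak are removed.

Scenario shifts are realized by moving the beams, not resampling the image.
For a parallel beam this is exact and reduces to a lateral displacement of
each spot axis; a material point's WEPL is unchanged by moving a parallel
beam.  Density-scale scenarios multiply the cached WEPL field, so one ray
trace per (beam, image) serves every scenario.  Influence matrices are
RBE-weighted (constant 1.1), thresholded at 1e-4 of each spot's maximum and
stored sparse.

## Robust optimization

The scenario set is the nominal scenario plus one scenario per
(direction, +-RRS) pair — range errors only in combination with shifts,
giving 1 + 2 x |directions| scenarios: 29 for the standard 14-direction 3-D
set (6 cube faces + 8 normalized vertices), 17 for the 8-direction 2-D set
used at the default geometry.  Optimization and evaluation sets come from
the same constructor.

Spot weights are nonnegative.  The clinical wish-list style multi-criteria
optimization is replaced by a two-level prioritized scheme:

1. **Robust coverage.**  Per scenario, target voxels are pulled toward
   their prescription quadratically (elective voxels may range up to the
   high prescription without penalty), with a strongly weighted quadratic
   hinge below 94% of prescription (weight 50, escalated x10 once if
   verification fails).  A ring (10 mm expansion of the elective target)
   receives a nominal-scenario overdose penalty.  After solving, V94% >=
   98% for both targets is verified directly on the scenario-set VoxMin;
   failure after escalation is reported as infeasible, never silently
   returned.  The quadratic pull targets the prescription rather than the
   94% level deliberately: it leaves ~6% dose margin above the coverage
   threshold, so the constraint is met with slack instead of balancing on
   the threshold.
2. **Prioritized organ-at-risk sparing.**  OAR mean doses (nominal scenario
   only, matching clinical practice for non-serial structures) are
   minimized in priority order with a small linear trade-off weight
   (3e-4/Gy); during these phases the coverage hinge weight is boosted x4.
   A candidate that breaks the verified coverage is rejected and the
   trade-off deterministically backed off (x0.25, up to 3 times).  Each
   optimized level is frozen as a constraint with 2% slack before the next.
   A light total-weight regularizer (1e-6) stands in for monitor-unit
   economy.

The solver is L-BFGS-B (bound-constrained quasi-Newton) from a uniform,
prescription-scaled initialization; iteration caps (200 feasibility, 100
per OAR phase) and a 1e-9 relative-objective tolerance are the convergence
budget, and the whole path is deterministic.  All phases are convex in the
weights; the lexicographic structure is approximate (penalty-based), which
is why the scenario-subset monotonicity property is verified at near-exact
solver settings on small structured problems rather than at production
settings.

## Evaluation

Every plan is forward-computed on the ground-truth image: the plan's beams
are rebuilt on the ground-truth RSP for the 1 mm / 3% evaluation scenario
set.  Robust target coverage is V94% read off the VoxMin composite
(elementwise scenario minimum); OAR mean doses come from the nominal
scenario and feed logistic NTCP models.  The shipped NTCP coefficients
(xerostomia-like: intercept -2.2, 0.054/Gy on parotid mean; dysphagia-like:
intercept -3.2, 0.058/Gy on constrictor mean) are editable configuration
chosen to give plausible baseline risks and slopes, not clinical truth; the
pipeline treats them as opaque parameters.

The population 90th percentile sorts from best to worst performer
(metric-specific direction: low coverage is bad, high NTCP is bad), takes
the fractional rank 0.9 x n counted toward the worst, and linearly
interpolates — for n = 23 this lands between the 20th and 21st worst, the
convention the evaluation chain is built around.  Paired strategy
comparisons use the two-sided Wilcoxon signed-rank test (exact for small
samples without ties), with the all-zero-differences case reported as
degenerate (p = 1) with a warning.

## Study design

The default study generates 23 phantoms (seeds 1–23 with derived CBCT and
anatomy-change seeds) and, per phantom, seven plans: the offline reference
planned on the drifted earlier anatomy at 3 mm / 3%, five CBCT-online plans
at 1 mm SRS with RRS in {3, 6, 8, 10, 12}%, and a ground-truth-online
reference at 1 mm / 3%.  All are evaluated on the ground truth at
1 mm / 3%.  Results are a long-format table (one row per phantom x
strategy) plus summaries: medians, best-to-worst 90th percentiles, counts
of phantoms below 95% coverage (strict inequality), NTCP differences vs the
offline baseline in percentage points with signed-rank p-values, and
per-OAR fractions of phantoms improved.

What the cohort does and does not show.  Phantoms with error-heavy CBCTs
show clean monotone coverage recovery with increasing RRS, and the
population tail (90th percentile, outlier counts) improves accordingly —
this is the mechanism the study exists to demonstrate.  Phantoms whose
error fields happen to lie away from the beam corridors saturate near full
coverage already at RRS 3%, so central statistics (medians) sit in a narrow
97–99% band where residual solver-level variation of a few tenths of a
percentage point dominates any RRS effect; a strict monotone trend in the
median is therefore not a robust property of this cohort (nor was the
median the carrier of the effect in the clinical motivation, where medians
were essentially flat between strategies).  Passing tests on this cohort
demonstrate mechanism and trend structure on synthetic anatomy; they do not
certify clinical dosimetric magnitudes.

## Numerical and degenerate-input conventions

HU values are clamped to [-1024, 3071] after corruption.  Rays that miss
the grid return empty WEPL profiles; voxels beyond the traced depth range
clamp to the last sample.  V94% uses a >= comparison at 0.94 x
prescription.  MAE/ME exclude voxels whose *reference* value is below
-960 HU and raise if nothing survives.  An all-zero paired difference
vector yields p = 1 with a warning rather than an error.  Masks are strict
booleans; nesting (ctv_high within ctv_low within external) is validated at
construction.  Runtime at the defaults: a single robust plan optimizes in a
few seconds on one CPU; the full 23-phantom, seven-plan study takes roughly
8–10 minutes.  These problem sizes (2-D grids, 17-scenario sets) were
chosen so a complete study is an interactive desk-scale computation.
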