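# Methods

`rehabmech` models how voluntary wheel-running rehabilitation relates to
the healing of plate-stabilized segmental femoral defects in rodents.
The pipeline has five analysis stages — activity-parameter extraction,
a linear PLS-DA baseline, genetic-programming symbolic regression, a
voxel finite-element (FE) strain surrogate, and healing-outcome
statistics — plus a synthetic-cohort generator that supplies inputs with
the statistical structure the analysis assumes.

## Activity parameters

Input is a per-second cumulative-distance stream from a wheel revolution
counter.  Six parameters are computed per day and averaged over weeks
1–3 of rehabilitation (callus formation begins around week 3, after
which activity and healing confound each other):

| parameter | unit | definition |
|---|---|---|
| distance | m/day | total cumulative-distance increase |
| duration | min/day | summed bout durations |
| bouts_per_day | 1/day | number of running bouts |
| bout_duration | s | mean bout duration |
| velocity | m/s | distance / running duration |
| rest | h | longest daily window with no distance change |

A bout starts at the first second with a distance change and ends when
`gap_seconds = 6` consecutive seconds elapse with no change.  Design
choices that the definitions leave open: velocity is day-wise (daily
distance over daily running time) rather than a mean of per-bout
velocities, which would be nearly collinear with the other parameters;
rest is the single longest idle window (the definition says "maximum"),
truncated at midnight day boundaries; an isolated movement sample is a
1-s bout.  An idle day has distance 0, rest 24 h, and *missing* (not
zero) velocity and bout duration; missing values are excluded from
weekly means.

## Synthetic cohort

The generator replaces the animal study's raw data.  It emulates:

* **Telemetry.**  A two-state (run/rest) renewal process on a 1-s grid:
  idle times exponential with mean `3600/bout_rate − bout_duration_mean`
  seconds, bout durations exponential, per-bout speed from a truncated
  normal.  Access-restricted profiles can only run between 20:00 and
  22:00; the cumulative distance is flat outside the window.  Three
  default profiles reproduce the observed ordinal structure — a
  low-distance group (2 h access, slow sparse bouts, ≈ 96 m/day
  expected), a restricted group (2 h access, dense bouts, ≈ 840 m/day,
  long daily rest), and an unrestricted group (24 h access, ≈ 905 m/day
  spread over the whole day, short rest).
* **Outcome response.**  End-point bone volume follows a "goldilocks"
  surface: `BV = bv_max · exp(−(d−d_opt)²/2σ²) · rest/(rest+k)` plus
  Gaussian noise truncated at zero — nonmonotone in daily distance,
  saturating in rest.  Defaults (`bv_max` 30 mm³, `d_opt` 600 m/day,
  σ 300 m/day, `k` 4 h, noise SD 1.5 mm³) put the optimum between the
  low-distance and restricted/unrestricted group means at rat
  femoral-defect bone-volume scale.  The planted feature cohort
  (n = 60) draws distance and rest as the informative variables and the
  other four parameters independently, so variable-selection claims can
  be scored against ground truth.
* **Defect volumes.**  Hounsfield-unit voxel grids: cortical rings at
  both ends, a gap of soft tissue, a central mineralized column filling
  a chosen fraction of the defect cross-section, and ellipsoidal ectopic
  clusters confined to the outer thirds of the gap (they add mineral
  volume but can never span the defect on their own).  Mineralized
  structures use 3000 HU (mapping to ≈ 1.4 GPa, above the mineralization
  threshold), soft tissue 30 HU, with additive intensity noise.
* **Reference cohort.**  Thirteen 3 mm defects (six low-distance, seven
  restricted), six designed unions.  Unions have no bridging column at
  week 2 and a 0.5–0.8 cross-section column by week 4 (0.9 by week 8);
  nonunions never bridge but accrue ectopic bone, so bone volume still
  rises.  Fixation-plate strain targets follow two synthetic two-point
  reference curves: union-like 500 → 350 µε and nonunion-like
  350 → 450 µε (weeks 2 → 4), with 8% per-subject jitter.  The curves
  stand in for instrumented-plate measurements that are not available in
  digital form; their shapes encode the observed pattern (union limbs
  load up early and stabilize; nonunion limbs stay unstable).

What the generator does **not** emulate: circadian structure beyond the
access window, counter glitches, correlated bilateral limbs, 2 mm
defects in the FE arm, irregular real defect geometry, or any
biological coupling from strain back to bone formation.  Passing tests
therefore demonstrate that the pipeline recovers *planted* structure,
not that the biological claims hold in new animals.

## PLS-DA

Features are z-scored and the 0/1 bridging response centered; latent
variables come from SIMPLS (the algorithm behind the reference
implementation cited for this analysis), with each LV's sign fixed so
its largest-magnitude loading is positive.  The classifier is nearest
class centroid in score space (the original classifier is unnamed).
Accuracy uses seeded stratified k-fold cross-validation; loading
confidence intervals are percentile 95% bootstrap over subjects with
per-replicate sign alignment to the full-data loadings, redrawing
degenerate (single-class) resamples.  R² is computed from the continuous
PLS prediction before classification.  The NIPALS implementation in
scikit-learn serves as an independent cross-check of the first latent
direction in the tests.

## Symbolic regression

A multi-objective genetic program evolves algebraic expression trees
over the six features with operators `{+, −, ×, protected ÷, integer
powers 2–3}`.  Protected division returns a configured constant (1.0)
whenever the denominator magnitude is below 1e-12.  Fitness is
`1 − R²` (clamped to [0, 1]) after *linear scaling*: each raw tree
output is regressed on the response (`y ≈ a·f(x) + b`) and the optimal
scale/offset are folded back into the stored tree.  Complexity is the
expressional *visitation length* — the sum of node counts over all
subtrees (a `pow` exponent counts as a leaf).  Features are z-scored
internally; the standardization is carried on each model so prediction
takes raw features.

Each of the (default ten) independent evolutions seeds its population
with every bare variable, every square, and pairwise products —
the building blocks interaction terms are assembled from — then ramped
half-and-half trees.  Selection is a size-4 tournament that compares raw
fitness 70% of the time and Pareto rank then complexity otherwise,
balancing accuracy pressure against parsimony.  Offspring arise from
subtree crossover, subtree mutation, and constant jitter; each
generation the most accurate offspring get a local Levenberg–Marquardt
refit of their scalar coefficients (a variable projection around the
analytic outer scaling), and the merged archive's best models receive a
deeper final refit.  A generation budget replaces the wall-clock budget
of interactive tools so runs are exactly reproducible; archives
deduplicate by canonical form (constants rounded to 6 significant
digits, commutative operands sorted) and keep all nondominated models
plus dominated ones up to a cap.

Knee selection supports two rules: the absolute strict-threshold filter
(complexity < 100 and fitness < 0.2, the thresholds quoted for the
original tool), and a relative rule — all models under the fitness cap,
keeping the `max_models` most accurate — because visitation length is
not on the same scale as the proprietary complexity score the absolute
threshold was chosen for.  The "robust models" filter discards models
whose fitness degrades by more than 0.05 when their scaling constants
are refit on a random 80% subset.  Ensembles report the member median
and the interdecile (10th–90th percentile, nearest-observation) range;
response surfaces flag cells as unsupported when the spread exceeds a
configured fraction of the center's range or the nearest training point
in standardized space is too far — the open/white "uncertainty" region.

## Voxel finite-element surrogate

Subject-specific strain in the regenerative niche is estimated with
small-strain isotropic linear elasticity on a structured grid of 8-node
trilinear hexahedra (one element per active voxel), replacing a
neo-Hookean tetrahedral contact model.  The simplification is justified
by the strain regime (defect strains ~1%, cortical strains ~100× lower)
and verified independently (patch test, uniaxial and bimaterial bars,
energy balance, manufactured-solution convergence).  Parts join through
shared grid nodes, standing in for tied-interface constraints.

Materials: healing-region voxels map intensity to modulus by
`E = 4.49e-4·(I − 19.5)^1.87` MPa for I ≥ 100 HU and E = 0.022 MPa
below (the discontinuity at 100 HU is intentional and preserved);
elements above 631.6 MPa are classified mineralized (strict inequality).
Constant regions: cortical 8803 MPa/0.33, trabecular 2169 MPa/0.33,
plate 525 MPa/0.40, risers 200 000 MPa/0.30; marrow is a hollow cavity.
Mapped defect tissue uses ν = 0.33 (unstated for the source data;
matches bone and avoids near-incompressible conditioning).

Geometry is parametric: hollow cortical diaphysis with trabecular end
caps, mid-shaft defect gap filled from the subject's intensity volume,
offset plate connected through riser blocks on each segment.  The
distal end face is fixed; the proximal face carries an axial pressure
with a linear in-plane gradient toward the plate side, integrating to
the applied force.  The plate "sensor" is the outer plate-face element
patch spanning the defect; load calibration finds the force whose peak
first-principal (tensile) patch strain matches a target in microstrain.
Because the model is linear, the production path calibrates by scaling
a single reference solve; a secant iteration is retained for interfaces
that need it.  The linear solver is a sparse direct factorization by
default at these problem sizes (preconditioned CG is available and
falls back to direct if it stagnates); solutions are verified by
residual check and work-energy balance.

Outputs are element-centroid strain tensors; compressive strain is the
negated third principal strain and shear strain is half the difference
of extreme principals.  Summaries are volume-weighted mean ± SD over
masks (whole defect, mineralized, non-mineralized, cortical); an empty
mask yields a flagged missing summary, never zero.

**Problem sizes.**  The reference cohort runs on a 0.5 mm grid
(10-voxel bone cross-section, ≈ 1100 elements, ≈ 15k dof per model),
chosen so a full 13-subject × 2-week cohort solves in seconds while
preserving the bridged/unbridged stiffness contrast; single-subject
demonstrations default to 0.3 mm (≈ 4600 elements).  The element budget
is capped at 1e5.

## Healing analysis

Bone volume is the mineralized-voxel volume inside a cylindrical VOI
centered between the bone ends — 2.5 mm long for 3 mm defects, 1.5 mm
for 2 mm — with radius defaulting to the cortical outer radius (left
unstated in the source protocol).  Bridging is scored algorithmically:
a 26-connected mineralized component touching both defect faces
(the original scoring was visual).  The union signature is the week-2 →
week-4 fold change of volume-weighted mean defect strain; FC < 1
(strict) predicts union, so FC = 1 is classified nonunion.  Regressions
of strain against later bone volume are ordinary least squares with a
two-sided slope t-test; defect-wide volume-weighted means are the
default predictor, with per-tissue (mineralized/non-mineralized)
summaries also emitted.

## Orchestration

A single integer seed derives independent per-stage substreams (SHA-256
of `seed:stage`), so stages rerun independently yet reproducibly.  The
configuration is schema-checked in one pass (all errors collected;
unknown keys warn), and each run writes a manifest with a configuration
hash and the artifacts each stage produced.  Telemetry CSVs store only
movement samples plus day endpoints, which is loss-free for the
activity metrics.

## Numerical notes and limitations

* Protected division and output clipping (±1e12) make expression
  evaluation total; NaNs are replaced by 0 during evolution, and
  ensemble members that go non-finite at a query point are excluded
  there and counted.
* Pareto-front extraction uses a sorted sweep; ties in both objectives
  are kept as mutually nondominated.
* The GP is stochastic: archive contents and knee counts vary by seed;
  determinism holds only at fixed seed and configuration.
* The FE surrogate has no contact, no orthotropy, no tetrahedra, no
  large deformation; voxelated cylinders have stair-stepped surfaces,
  so absolute strain magnitudes are grid-dependent even though
  contrasts (bridged vs unbridged, defect vs cortical) are robust.
* Fold-change concordance is exact on the designed cohort because the
  generator plants a large bridging contrast; real cohorts sit closer
  to the FC = 1 boundary.
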