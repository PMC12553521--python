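# rehabmech

Subject-specific multivariate analysis of how rehabilitation activity
relates to segmental bone-defect healing.

Severe long-bone defects are stabilized surgically and then
rehabilitated, but the prescription — how far, how often, and with how
much rest an injured limb should be loaded — is largely guesswork.  In
rodent models the question is quantifiable: wheel revolution counters
yield a per-second cumulative-distance stream for every animal, microCT
gives longitudinal bone volume in the defect, and finite-element (FE)
models estimate the mechanical strain the regenerating tissue actually
experiences.  `rehabmech` implements that full analysis chain for
plate-stabilized femoral defects, plus a seeded synthetic-cohort
generator so every stage is testable without animal data:

* **activity** — six rehabilitation parameters per day from telemetry:
  distance (m/day), duration (min/day), bouts/day, mean bout duration
  (s), velocity (m/s), and rest (h, the longest idle window).  A bout
  ends when 6 consecutive seconds pass with no distance change.
* **plsda** — linear baseline: SIMPLS partial least squares
  discriminant analysis of union/nonunion on the z-scored features,
  with bootstrap loading CIs and stratified cross-validated accuracy.
* **symreg** — nonlinear engine: multi-objective genetic-programming
  symbolic regression trading accuracy (fitness `1 − R²`) against
  expressional complexity (visitation length), with Pareto archives,
  knee selection, variable-presence analysis, and model-ensemble
  response surfaces carrying an explicit uncertainty envelope.
* **fe** — voxel finite elements: microCT intensity `I` (HU) maps to
  modulus `E = 4.49·10⁻⁴ (I − 19.5)^1.87` MPa for `I ≥ 100` HU
  (0.022 MPa below; mineralized where `E > 631.6` MPa), embedded in a
  parametric femur–plate–riser model; the load is calibrated so the
  simulated fixation-plate strain matches a measured target, and the
  defect's compressive (−third principal) and maximum-shear strains are
  summarized as volume-weighted mean ± SD.
* **healing** — cylindrical-VOI bone volume, 26-connected bridging
  detection, strain-vs-bone-volume regressions across timepoints, and
  the week-2 → week-4 strain fold change: `FC = ε̄(wk4)/ε̄(wk2) < 1`
  predicts union.

See `docs/methods.md` for the models, assumptions, and numerical
choices.

## Worked example

Generate the 13-subject reference cohort (six designed unions), run the
strain pipeline for weeks 2 and 4, and score the fold-change signature:

```python
from rehabmech.synthetic import CohortConfig, simulate_cohort
from rehabmech import healing

bundle = simulate_cohort(CohortConfig(seed=0))
records = healing.analyze_cohort(bundle)
report = healing.cohort_report(records)

t = report["subjects"]
for _, r in t.head(4).iterrows():
    print(f"{r.subject_id}  union={bool(r.designed_union)}  "
          f"strain wk2={r.strain_wk2:.4f} wk4={r.strain_wk4:.4f}  "
          f"FC={r.fold_change:.2f}  predicted_union={bool(r.predicted_union)}")
print(f"fold-change concordance: {report['fold_change_concordance']:.2f} "
      f"({report['n_union']}/{report['n_subjects']} designed unions)")
reg = report["regressions"]["wk4_strain_vs_wk8_bv"]
print(f"week-4 strain vs week-8 BV: slope={reg.slope:.1f}, "
      f"R^2={reg.r_squared:.2f}, p={reg.p_value:.2e}")
```

prints

```
low01  union=False  strain wk2=0.0089 wk4=0.0109  FC=1.22  predicted_union=False
low02  union=False  strain wk2=0.0085 wk4=0.0104  FC=1.22  predicted_union=False
low03  union=False  strain wk2=0.0089 wk4=0.0110  FC=1.23  predicted_union=False
low04  union=False  strain wk2=0.0079 wk4=0.0117  FC=1.48  predicted_union=False
fold-change concordance: 1.00 (6/13 designed unions)
week-4 strain vs week-8 BV: slope=-3854.9, R^2=0.98, p=2.48e-11
```

Reading it: these low-distance nonunion subjects carry ~0.9% mean
compressive strain in the defect at week 2 that *rises* by week 4
(fold change above 1) because no mineralized bridge forms to share
load; designed unions (rows further down the table) drop from ~1.2% to
~0.2% (fold change well below 1).  The prediction "fold change < 1 ⇒
union" matches the designed outcome for all 13 subjects, and subjects
with lower week-4 strain end up with more bone at week 8 (negative
slope), whereas the week-2 correlation has the opposite sign — early
strain stimulates, late strain signals instability.

The same run is available from the shell:

```bash
rehabmech all --seed 0 --out runs/demo        # every stage
rehabmech symreg --seed 0 --out runs/demo     # one stage
```

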