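# Methods

## Pipeline model

`volscribe` converts per-structure brain volumes into radiologic sentences
in four stages, each of which is an explicit, auditable object.

**Anatomic hierarchy.** The structure vocabulary is a DAG: level-0 base
labels (gyri, nuclei, ventricles, deep sulci) and superstructures whose
volume is the bottom-up sum of their children.  A base label may appear
under several independent superstructures, but the children of any one
superstructure must span pairwise-disjoint base sets, so no volume is
double-counted within it; this is validated at construction, along with
acyclicity.  Aggregation is idempotent and order-independent.  The shipped
`default_hierarchy()` is a deliberately compact stand-in for a full
multi-atlas parcellation: 40 base labels (17 per-hemisphere tissue labels
grouped into the five classic lobes, plus caudate, lateral/third
ventricles, deep sulci, cerebellum, brainstem) and 12 superstructures (10
lobes, 2 hemispheres).  It carries every level the reporting rules consume;
production use would supply a richer hierarchy as a JSON file of
`{id, name, laterality, tissue_class, children}` records.

**Normative model.** Volumes are normalized to ratios `r = V/D`, with `D`
the sum of all base-level volumes (tissue + ventricles + deep sulci),
computed once per case; ratios are used because their normal-range
variability across head sizes and protocols is much smaller than raw
volumes'.  Per structure, the normative model is OLS of ratio on age with a
homoscedastic residual SD `σ = √(RSS/(n−2))`; all structures are solved in
one vectorized least-squares.  Modeling choices:

* age-linear, age-only: no nonlinear curves, sex, or site covariates;
* raw ratios, not log-ratios;
* a single pooled residual SD rather than an age-dependent one;
* fitted SDs are floored at 1e-12 so degenerate noise-free training data
  still yields finite z-scores;
* scoring a case outside the control age range sets an `extrapolated` flag
  but still returns values — clinical cases need not fall inside the
  normative span;
* structures absent from the model are marked missing (NaN z), not errors.

z-scores are `(r − r̂(age))/σ`: negative for tissue atrophy, positive for
ventricular or sulcal enlargement.  `NormativeResults` serializes to JSON
losslessly and carries classical OLS standard errors for recovery
diagnostics.

**Clinical knowledge filter.** Default: 20 reported structures (16 tissue —
2 hemispheres, 10 lobes, hippocampi, caudates — and 4 enlargement-direction
entries — lateral/third ventricles, deep sulci), threshold T = 2.0,
prominence budget 2 lobes.  Detection semantics:

* hemispheric state from `z(hemisphere_L/R) < −T` (left / right /
  bilateral / none);
* per atrophic hemisphere, a "prominent" clause when the affected lobes
  form a nonempty *proper* subset of its five lobes with at most
  `prominence_max_lobes` members ("localized in a small number of lobes"
  is operationalized as this proper-subset-with-budget rule);
* "specific" lobar-combination sentences only when *neither* hemisphere is
  atrophic (the suppression rule); identical left/right combinations merge
  into one "bilateral" sentence;
* direct triggers for non-lobar tissue structures at `z < −T`, enlargement
  triggers at `z > +T`.

`enumerate_rule_table` expands this logic into explicit Boolean
conjunctions over the 12 hemisphere/lobe indicators, generated from the
sentence definitions rather than from the detector, so exhaustive
agreement over all 2^12 assignments is a genuine audit (it holds, and is
asserted in the test suite and the acceptance script).  The audit table
emits three hemispheric patterns (left, right, bilateral); the
all-normal assignment emits nothing.  Lobar "specific" combinations are
generated programmatically for every emittable subset rather than
hand-enumerated.  Sentence wording lives in a JSON dictionary of
`str.format` templates and structure terms, so phrasing (or language) can
be swapped without code changes; a missing template or term is a hard
error naming the key.

**Evaluation.** Two finding sources are compared per (case, term) cell
over a fixed universe, so counts always total `cases × universe`.  Metrics
with zero denominators return NaN, never a silent zero.  Cohen's kappa
uses marginal-product expected agreement.  Majority voting is positive at
≥ 2 of exactly 3 raters ("more than 2" read as 2-of-3; unanimity would
contradict the consensus counts such a design produces).  Group "mean"
statistics over rater pairs are computed on the pooled (summed) 2×2
tables, which is how the bundled reader-study tables' printed means are
reproduced exactly.  The discrepancy categorizer walks an ordered decision
tree (unrepresentable term → 1; automated-only structure → 2-1;
filter-dropped structure → 2-2; z-supported but rule-suppressed → 3;
ancestor/descendant extent mismatch → 4; segmentation annotation → 5;
else 6-FP/6-FN by direction), with a term-alias table mapping report
phrasing (including multi-lobe phrases) onto hierarchy id sets.  Category
5 encodes a radiologist's visual judgment and therefore enters via an
annotation flag, never automatically.

## Synthetic cohort generator

The generator defines the study conditions for all calibration and
recovery claims.  Each base structure except one carries an age-linear
Gaussian ratio model, drawn independently.  The deep-sulci label closes
the partition as `1 − Σ(other ratios)`: total brain volume is exactly the
sum of base volumes, every modeled structure's realized ratio equals its
drawn value (so marginal models are exact, not approximate), and tissue
loss surfaces as sulcal widening, as on real images.  Defaults:

* 179 controls, ages uniform on [20, 95] — a realistic multi-site
  normative cohort;
* tissue mean ratios decline by 0.08% of their age-60 value per year;
  ventricles grow by 1.2% per year (they roughly triple across adult
  life); per-structure noise SD is 5% of the age-60 mean, placing the
  hippocampal ratio near 0.0037 with SD ≈ 1.9e-4;
* total brain volume N(1.45e6 mm³, 5e4 mm³) per case;
* ratios are truncated at 1e-8 (the Gaussian mass below is negligible at
  these settings); specs whose *mean* ratios go non-positive anywhere in
  the age range are rejected outright.

Injection: a target's mean is shifted by `k` SD of its own marginal model;
shifts aimed at superstructures are distributed over base descendants
proportionally to mean ratio, and a shift aimed at the remainder label is
pushed out of tissue the same way.  Shifts propagate coherently: a −3 SD
frontal-lobe injection deterministically moves its parent hemisphere by
`3·σ_lobe/σ_hemisphere` (≈ −2.2 at defaults), so the ground truth for that
injection is hemispheric atrophy with frontal prominence, not a
lobar-specific sentence — a property the tests assert rather than avoid.

`simulate_patient` has a `subject_noise` switch.  With it (default), the
case is a random subject with shifted means — realistic, and used for null
calibration.  Without it, the case sits exactly at the shifted means (a
noise-free pathology phantom).  The distinction matters quantitatively:
with full between-subject noise, the per-structure probability of
triggering at T = 2 under a −3 SD shift is Φ(1) ≈ 0.84, and the chance
that *no* unshifted structure among ~20 reported ones falsely triggers is
only ≈ 0.63 per case.  Pipeline-recovery experiments that demand
near-certain, exactly-matching assertion sets are therefore defined on the
phantom: replicate randomness comes from refitting the normative model on
a fresh control cohort each time, which isolates the systematic behavior
of the aggregation/normative/rule machinery from subject variability.  The
realistic per-patient sensitivity (~84% per structure at −3 SD) is the
number to quote for individual noisy patients.

## Calibration claims and experiment sizes

* **Null trigger rate.** 10,000 simulated normal cases scored against a
  model fitted on 500 controls; the mean per-structure trigger rate in
  each structure's trigger direction sits at the normal tail beyond T = 2
  (≈ 0.0228).  The *mean* across reported structures is the calibrated
  quantity: any single structure's rate is `Φ(−2·σ̂/σ)` with σ̂ carrying a
  CV of `1/√(2(n−2))` ≈ 3.2% at n = 500, so individual structures
  legitimately wander within roughly [0.016, 0.031] even when the engine
  is exactly correct, while the mean concentrates tightly.  Scoring
  against the exact generative model instead (no estimation noise) puts
  every structure individually at the tail, and the suite checks that too.
* **Recovery.** 500 replicates, each fitting on a fresh 500-control
  cohort, of a bilateral hippocampal −3 SD / lateral-ventricle +3 SD
  phantom at age 72: ground-truth assertion set recovered, and matched
  exactly, in ≥ 95% of replicates (in practice ~100%; failures would
  require a ~50% misestimate of a residual SD).
* Experiment sizes (500 controls, 10,000 null cases, 500 replicates) were
  chosen so Monte-Carlo error is a small fraction of each claimed margin;
  all experiments run in seconds because cohort simulation and fitting
  stay in matrix form end to end (`simulate_and_fit` is verified
  numerically identical to the volume-table round trip).

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure the pipeline relies
on — age-linear ratio trends, marginal Gaussian noise, hierarchy-consistent
volumes, conservation of total volume under atrophy — so passing tests
demonstrate correct aggregation, fitting, scoring, rule logic and
end-to-end plumbing.  It does not emulate segmentation error, scanner or
protocol effects, inter-structure covariance (a hook exists in the design
but structures are drawn independently, matching the marginal z-score
model), non-Gaussian pathology, or radiologists' perceptual thresholds.
Published clinical-cohort figures such as per-category error percentages
or ventricular z-scores of specific patients depend on real scans and
human annotations and are deliberately out of reach; the bundled
reader-study contingency counts are carried as fixed inputs for the
agreement-metric computations only.

## Numerical and degenerate-input choices

* OLS via `numpy.linalg.lstsq` on the joint (n × p) ratio matrix;
  cross-checked against statsmodels in the tests.
* Residual-SD floor 1e-12; superstructure aggregation exact sums (relative
  float error ~1e-16, asserted at 1e-9 or better in round-trip tests).
* Constant-age cohorts, cohorts smaller than 3, zero denominators,
  missing base labels, hierarchy cycles and double-counted children are
  hard errors naming the offender.
* Ties at exactly z = −T do not trigger (strict inequality), matching the
  strict `<` of the rule definitions.
* Lobe phrases join stems in canonical lobe order
  (frontal, parietal, temporal, occipital, limbic):
  "front-temporal", "parieto-occipital".

## Known limitations

* The default hierarchy is a compact approximation; the exact membership
  of a production atlas's superstructure levels must be supplied by the
  user.
* The prominence definition ("proper subset of ≤ 2 lobes") is one
  reasonable operationalization of "localized in a small number of lobes";
  the budget is configurable.
* Free-text report coding into per-structure findings is upstream, manual
  work; the evaluator consumes already-coded TSV findings.
* Error category 5 (segmentation quality) cannot be automated and must be
  annotated by a human reader.
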