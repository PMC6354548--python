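# volscribe

Automated radiologic sentences from regional brain MRI volumetry.

Radiologists reading a T1-weighted (MPRAGE) brain scan reduce millions of
voxels to a handful of sentences about atrophy and ventricular enlargement.
`volscribe` implements that reduction for quantitative volumetry output: it
takes per-structure volumes (e.g. from a multi-atlas segmentation), rolls
them up through an anatomic ontology into the units radiologists actually
name (lobes, hemispheres), judges each against an age-corrected normative
model, and triggers templated sentences through a curated clinical rule
set.  It also ships the evaluation machinery needed to compare such
automated sentences against coded human report findings, and a synthetic
cohort generator so the whole pipeline can be validated end to end with
known ground truth.

## Method

1. **Anatomic aggregation.** Base structures (gyri, nuclei, ventricles,
   deep sulci) are summed bottom-up into superstructures defined by a
   DAG-shaped hierarchy: `V(s) = Σ_children V(c)`.
2. **Normative z-scores.** Each structure's volume is normalized by the
   total brain volume `D` (all base tissue + ventricles + deep sulci):
   `r = V/D`.  On a control cohort, per structure, OLS of `r` on age gives
   `r̂(age) = α + β·age` with residual SD `σ = √(RSS/(n−2))`, and a patient
   scores `z = (r − r̂(age)) / σ`.  Tissue atrophy gives `z < 0`,
   ventricular/sulcal enlargement `z > 0`.
3. **Clinical knowledge filter.** Only a curated list of 20 structures (2
   hemispheres, 10 lobes, hippocampi, caudates, ventricles, deep sulci) can
   produce sentences, at threshold `|z| > 2`:
   *direct* triggers (`z(hippocampus_L) < −2` → "The left hippocampus has
   atrophy."), *relational* triggers (left/right/bilateral hemispheric
   atrophy, with a nested "prominent" clause when atrophy within an
   atrophic hemisphere is confined to at most two lobes), and *combination*
   triggers ("specific" lobar-pattern sentences, suppressed whenever a
   hemisphere-level sentence fires).  The full rule set can be expanded
   into an explicit Boolean table (`enumerate_rule_table`) and is verified
   equivalent to the detector over all 4,096 indicator assignments.
4. **Evaluation.** Automated and human findings are compared per
   (case, structure) cell over a fixed universe: accuracy, sensitivity,
   precision, specificity and Cohen's kappa from the 2×2 counts, a 2-of-3
   majority-vote consensus rater, and an ordered six-branch taxonomy that
   classifies each discrepancy (undefined term; structure not routinely
   examined / dropped by the filter; rule-logic suppression; hierarchy
   extent mismatch; segmentation quality; triggering threshold).

## Worked example

```python
import volscribe as vs

h = vs.default_hierarchy()
spec = vs.CohortSpec.default(seed=42)          # 179 controls, ages 20-95
norms = vs.fit_normative(vs.simulate_controls(spec, h), h)

atrophy = vs.AtrophySpec({"hippocampus_L": -3.0, "hippocampus_R": -3.0,
                          "lateral_ventricle_L": 3.0}, pattern_name="ad_like")
case, truth = vs.simulate_patient(spec, atrophy, age=74.0, seed=11, h=h)

z = norms.zscore(case, h)
for sid in ("hippocampus_L", "hippocampus_R", "lateral_ventricle_L"):
    print(f"z[{sid}] = {z.z[sid]:+.2f}")
report = vs.render_report(vs.detect_pattern(z, vs.ClinicalKnowledgeFilter.default()))
print(report.to_text())
```

prints

```
z[hippocampus_L] = -3.16
z[hippocampus_R] = -3.32
z[lateral_ventricle_L] = +3.50
There is right temporo-occipital lobe specific atrophy.
The left hippocampus has atrophy.
The right hippocampus has atrophy.
The left lateral ventricle is enlarged.
```

All three injected abnormalities are recovered.  The temporo-occipital
sentence is a chance triggering: this simulated patient's right temporal
and occipital ratios happened to fall just past −2 by subject noise, which
is exactly the threshold-related false-positive mode that dominates
disagreement between automated and human reports.

The same pipeline is available from the shell:

```sh
volscribe simulate --n-controls 179 --seed 42 --out-controls controls.csv \
    --atrophy atrophy.json --age 74 --out-case case.csv
volscribe build-norms --controls controls.csv --out model.json
volscribe score --cases case.csv --model model.json --out z.csv
volscribe report --zscores z.csv --out-sentences report.txt --out-assertions report.json
volscribe evaluate --counts --out metrics.tsv
```

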