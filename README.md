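# msofa

Severity-of-illness scoring for ICU patients: the original Sequential Organ
Failure Assessment (SOFA) and a bedside **modified SOFA (MSOFA)** that needs
no laboratory, plus the full diagnostic-accuracy pipeline used to compare the
two as predictors of ICU mortality.

## Who this is for

Intensive-care researchers and biostatisticians who want to (a) compute SOFA /
MSOFA panels from patient-day physiology, (b) evaluate any severity score
against a binary outcome with ROC methodology, and (c) exercise the whole
pipeline on reproducible synthetic cohorts when no patient-level data can be
shared.

## The scores

Both instruments grade six organ systems 0–4 and sum to a 0–24 total
(1–2 = dysfunction, 3–4 = failure):

| system         | SOFA (laboratory)                  | MSOFA (bedside)                     |
|----------------|------------------------------------|-------------------------------------|
| respiratory    | PaO₂/FiO₂                          | SpO₂/FiO₂ (pulse oximetry)          |
| coagulation    | platelet count                     | petechiae/purpura (2), spontaneous bleeding (4) |
| cardiovascular | MAP + vasoactive dose              | same                                |
| liver          | total bilirubin                    | scleral jaundice (2), skin jaundice (4) |
| CNS            | Glasgow Coma Scale                 | same                                |
| renal          | creatinine / daily urine           | hourly urine output, mL/kg/h        |

FiO₂ is always the inspired-oxygen *fraction* (55% oxygen is written 0.55).
Repeat same-day measurements aggregate by the worst-of-day rule (element-wise
maximum of the subscores).  All band edges live in `msofa/bands.py`.

## The evaluation statistics

A score *S* is evaluated against mortality through the empirical ROC curve
(positive call: *S* ≥ threshold, thresholds at midpoints of distinct observed
values).  The area under the curve equals the Mann–Whitney concordance
P(S_deceased > S_survived) + ½P(tie); its standard error and the paired
z test comparing two scores on the same patients use the DeLong placement-value
construction.  Operating cut-offs maximize Youden's J = sensitivity +
specificity − 1; at a cut-off the package reports the 2×2 table, sensitivity,
specificity, PPV, NPV and the diagnostic odds ratio (TP·TN)/(FP·FN).
Predictive values can also be obtained from (sensitivity, specificity,
prevalence) by Bayes' rule.

## Worked example

```python
from msofa import default_calibration, generate_score_cohort, empirical_roc

cohort = generate_score_cohort(default_calibration(seed=1))
t0 = cohort[cohort.timepoint == "T0"]
roc = empirical_roc(t0.msofa, t0.outcome)
print(f"MSOFA admission AUC {roc.auc:.3f} (95% CI {roc.ci95[0]:.3f}-{roc.ci95[1]:.3f})")
```

prints

```
MSOFA admission AUC 0.836 (95% CI 0.780-0.892)
```

i.e. at ICU admission the bedside score correctly ranks a randomly chosen
deceased patient above a randomly chosen survivor 83.6% of the time.  The
scripts in `examples/` walk through single-patient scoring
(`score_bedside_panel.py`), full cohort evaluation with paired AUC comparison
(`simulate_and_evaluate.py`), and the CSV → score → report file pipeline
(`physiology_pipeline.py`).

The same pipeline is available from the shell:

```bash
msofa simulate --out cohort.csv --seed 1
msofa score    --input cohort.csv --out scores.csv
msofa evaluate --input scores.csv --out report/
```

(`msofa report` composes all three.)  Outputs are CSV plus a plain-text
report; every file carries a provenance header with the seed, a config hash
and the tool version.

## Synthetic cohorts

No patient-level data accompany the study this package models, so
`msofa.cohort` simulates them at two levels: bivariate-normal (SOFA, MSOFA)
totals calibrated to the published two-group means/SDs (250 patients, 78
deceased / 172 survived, cross-instrument correlation 0.95), and raw bedside
physiology sampled inside the band tables so that scoring reproduces a drawn
target panel exactly.  See `docs/methods.md` for what these cohorts do and do
not emulate.

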