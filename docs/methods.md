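# Methods

## Scoring model

Both instruments map raw physiology to six ordinal organ grades (0–4) through
band tables and sum them to a 0–24 total.  The SOFA tables are the canonical
published definition: PaO₂/FiO₂ for respiration (grades 3–4 require
respiratory support, otherwise the grade caps at 2), platelets ×10³/µL for
coagulation, MAP plus vasoactive dose bands (dopamine ≤5 / >5 / >15,
epinephrine or norepinephrine ≤0.1 / >0.1 µg/kg/min) for circulation, total
bilirubin for liver, GCS for CNS, and the worse of the creatinine band and the
daily-urine criterion (<500 mL/day → 3, <200 mL/day → 4) for kidney.

The bedside instrument replaces each laboratory component with an observation
available without a laboratory:

* **respiratory** — SpO₂/FiO₂ with FiO₂ as a fraction.  The source
  description fixes the ratio but not its numeric thresholds; we adopt the
  published SpO₂/FiO₂ banding from the modified-SOFA literature
  (>400 / 315–400 / 235–314 / 150–234 / <150, support rule as in SOFA).
* **coagulation** — a three-level clinical grade: no bleeding signs (0),
  petechiae/purpura/ecchymosis (2), spontaneous bleeding (4).  Grades 1 and 3
  are unreachable by construction.
* **liver** — jaundice grade: none (0), scleral (2), skin (4).
* **renal** — hourly urine output normalised to weight.  Thresholds
  (≥0.5 / 0.3 / 0.2 / 0.1 mL/kg/h) anchor to standard oliguria conventions and
  span the full 0–4 range; they are declared defaults, isolated with every
  other edge in `msofa/bands.py` (left-closed on the worse side).

Missing data are never imputed: a laboratory value absent from a bedside-only
record blocks SOFA scoring with an error naming every unscorable system, and
leaves MSOFA unaffected.  Worst-of-day aggregation is the element-wise maximum
of repeated panels — a commutative, associative, idempotent lattice join — with
the total recomputed from the maxima.

## Evaluation statistics

Death is the positive class; a score calls a patient positive when it is at or
above a threshold.  Candidate thresholds are midpoints between consecutive
distinct observed scores plus sentinels beyond the extremes, which is why
half-integer cut-offs (e.g. 9.5) arise from integer totals.  The trapezoidal
area under the (1−specificity, sensitivity) polyline equals the Mann–Whitney
concordance with ties counted ½; the package computes both and tests assert
their equality to 1e−12.  The AUC standard error uses the DeLong
placement-value variance; the 95% CI is Wald, truncated to [0, 1].  Two scores
measured on the same patients are compared with the correlated (paired) DeLong
z statistic — the covariance of the placement values enters the variance of
the difference — with a two-sided normal p-value.  Comparing a score with
itself is defined as z = 0, p = 1; a non-zero contrast with degenerate
placement variance raises instead of dividing by zero.

Operating points maximize Youden's J with ties broken toward the lower
threshold (higher sensitivity).  The diagnostic odds ratio is reported as
infinite when FP·FN = 0 with a non-degenerate table, NaN when doubly
degenerate.  Predictive values follow Bayes' rule from sensitivity,
specificity and prevalence and exactly reproduce the direct 2×2 ratios when
the three inputs derive from one integer table.  Group contrasts use Welch's
unequal-variance t-test; associations use the product-moment correlation with
the t-transform p-value.  P-values are two-sided throughout; no
multiple-testing correction is applied.

## Synthetic cohorts

The study cohort is available only as printed group summaries, so the
generator is a two-group Gaussian model, not a re-creation of real patients:

* **score level** — per patient and timepoint, a bivariate-normal
  (SOFA, MSOFA) pair with the published group means/SDs (deceased n=78 vs
  survived n=172 at admission, 24 h and 48 h) and cross-instrument correlation
  ρ = 0.95, the midpoint of the published 0.942–0.972 range.  Totals are kept
  unrounded for evaluation by default; an optional flag rounds to integers and
  clips to [0, 24], which moves the AUC by <0.01 at these separations.
* **physiology level** — a target MSOFA total is drawn from the same group
  normal (rounded, clipped), apportioned over the six organs by
  largest-remainder apportionment on Dirichlet-jittered weights with the
  coagulation/liver grades remapped to the nearest even level (the unit
  difference is compensated on another organ, so totals are preserved
  exactly), and raw physiology is then sampled uniformly strictly inside the
  band implying each grade.  Laboratory variables are sampled in the band of
  the same clinical grade, so SOFA totals track MSOFA totals (r > 0.85 by
  test, in practice ≈0.99 — higher than the published 0.94–0.97 because both
  instruments share the drawn grade exactly).
* Demographics (sex within outcome group, traumatic cause cohort-wide, and the
  78/172 outcome split itself) are assigned by exact count plus a seeded
  permutation, so the published proportions (31.2% deceased, 40.4% traumatic)
  are reproduced identically at any seed.  The printed traumatic/nontraumatic
  counts (101/140) do not sum to 250; we keep 101 traumatic and assign the
  remaining 149 as nontraumatic.

What the generator does **not** emulate: within-patient correlation across
timepoints (group summaries per timepoint are all that is published, so draws
are independent across times), organ-level dependence structure beyond a
shared total, length-of-stay or cause-of-death processes, and any
non-Gaussian shape of real score distributions (real totals are bounded,
integer and typically right-skewed).  Passing tests therefore demonstrate
correctness of the scoring and evaluation machinery under the calibrated
model, not clinical validity on real patients.

## Numerical choices

* One `numpy.random.default_rng(seed)` instance drives all randomness per
  generator call; equal seeds give bit-identical cohorts.
* ROC integration sorts polyline vertices by (FPR, TPR) so simultaneous
  sensitivity/specificity jumps at tied scores integrate as the correct
  staircase.
* Physiology sampling keeps a margin of at least half a unit (one whole unit
  for ratios) from every band edge, so floating-point round trips through
  ratio arithmetic cannot cross a boundary.
* Validation is eager: snapshots reject out-of-range inputs at construction
  (FiO₂ given as a percentage, GCS outside 3–15, negative doses), and the CSV
  reader reports every parse failure with its row and column before raising.

## Default problem sizes

The test suite and the acceptance script use the study-scale cohort (250
patients × 3 timepoints) for calibration checks, 10,000 patient-timepoint
records for the physiology round-trip audit, 1,000 replicates for the paired-z
type-I-error calibration at n = 78/172, and dense 500–800-point grids for the
band-table sweeps.

## Known limitations

* The bedside respiratory and renal thresholds are declared defaults (see
  above); a site using different oliguria or saturation conventions should
  edit `bands.py`.
* Vasoactive dose banding assumes the canonical SOFA bands; local titration
  policies are not modelled.
* The paired z test relies on asymptotic normality; with very small cohorts or
  near-perfect separation the placement variance degenerates and the package
  raises rather than reporting an unstable statistic.
* PPV/NPV printed from rounded sensitivity/specificity/prevalence inputs can
  disagree with the exact 2×2 values by a few tenths of a percentage point;
  the package always reports computed values and does not force agreement with
  any published rounding.
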