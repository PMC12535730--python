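# Methods

This note documents the models, conventions and numerical choices behind
`copdrisk`, in the order data flows through the package.

## Score calculators

**Band lookup and rounding.** All banded vital-sign points (the NEWS rows
of the composite's point table) are defined on values at the table's
printed precision: one decimal for temperature, integers for heart rate,
SpO₂, respiratory rate and systolic blood pressure. Measurements are
rounded half-even to that precision before lookup, which makes the bands
exhaustive and mutually exclusive over the physiologic domain (a recorded
35.05 °C rounds to 35.0 and falls in the ≤ 35.0 band). Band edges are
inclusive on both printed endpoints.

**Threshold conventions.** Elevated BUN is ≥ 8.9 mmol/L (the canonical
unit; 8.9 mmol/L of urea nitrogen ≈ 25 mg/dL, and a conversion helper at
1 mmol/L = 2.801 mg/dL is provided for mg/dL sources — equality at exactly
8.9 is scored as elevated and logged). Acidemia is pH < 7.30 and
eosinopenia is eosinophils < 0.05 × 10⁹/L, both strict. The BAP-65 pulse
criterion "> 109/min" is implemented as heart rate ≥ 110, identical on
integer measurements. The age criterion is ≥ 65. Ages 18–40 are below the
composite's lowest printed band (41–64); they score 0 age points and emit a
warning that the record is outside the score's derivation range.

**NEWS consciousness dialect.** Cohort records carry a binary
altered-mental-status flag rather than the four-level AVPU scale, so the
NEWS consciousness item is 3 when the flag is set and 0 otherwise. This is
a documented dialect: any patient not alert scores 3 in standard NEWS, so
the mapping only coarsens the source of the "not alert" judgment.

**Composite structure.** The composite is computed by direct lookup of its
thirteen-parameter point table. Its structural identity — total =
6·(age ≥ 65 + altered mental status + elevated BUN) + (NEWS minus the
consciousness item) + 4·DECAFm — is *not* used in the implementation; it is
verified as a property test over randomized records, so the table and the
three source calculators check each other.

**Raw values vs flags.** When both a raw value (pH, eosinophils) and its
threshold flag are present, the raw value wins. One corner follows: a
record carrying only a flag, whose raw value is later imputed, is scored
from the imputed raw value. The simulator always generates consistent
raw/flag pairs, so the corner arises only with inconsistent hand-built
inputs.

**Missing inputs.** A score whose contributing field is unresolvable raises
an incomplete-score error rather than contributing silent zeros; cohort
scoring records such patients as NaN with a per-score completeness flag,
and reports per-score missing counts always computed on the raw,
pre-imputation cohort.

## Imputation

Missing admission parameters are filled by k-nearest-neighbor imputation
(default k = 10) before scoring — imputation acts on raw parameters, never
on score totals. Distance is Gower-type over pairwise-observed features:
range-normalized absolute difference for continuous fields, 0/1 mismatch
for flags and sex, averaged over the features both records observe (pairs
sharing no feature are at infinite distance). Continuous cells take the
median of the k nearest donors (medians bound the influence of outlier
donors); flags take the majority vote. All ties — equal distances and split
votes — resolve toward the lowest record index, making the imputer fully
deterministic. Outcome fields are excluded from the feature set so the
imputation cannot leak the endpoint later used for validation. The
raw/flag pairs (pH/acidemia, eosinophils/eosinopenia) enter the distance
once, through the raw value; an imputed raw value refreshes a missing flag.

The complete-case sensitivity analysis is handled by the `complete_only`
scoring policy, not by an alternative imputer; multiple imputation and
model-based (EM/MICE) approaches are out of scope.

## Evaluation

**AUC and DeLong inference.** The AUC is the normalized Mann–Whitney
statistic computed from placement values with ties credited ½; its variance
follows DeLong's structural components (sample variances of the positive
and negative placements over m and n), and the paired Z-test for two scores
on the same patients uses the analogous covariance of shared components.
Degenerate cases are explicit: identical rankings give z = 0, p = 1 with a
degeneracy flag, and fewer than two cases in either class makes the
variance of a difference non-estimable (flagged, not guessed). The ROC
curve arrays themselves come from scikit-learn; the package's placement
AUC is verified in tests against brute-force pair counting and against the
curve's trapezoidal area.

**Confidence intervals.** Default 95% CI is auc ± 1.96·SE truncated to
[0, 1]. A logit-scale interval (transform, expand, back-transform) is
available by flag; it produces the asymmetric intervals expected when the
AUC approaches 1 with few events.

**High-risk threshold.** The third quartile of the cohort's score
distribution, with quartiles by linear interpolation between order
statistics (the common default of mainstream statistical environments),
and high-risk defined as score strictly above it. On integer scores a
mid-gap Q3 (e.g. 18.5) therefore equals "≥ next integer". With heavy ties
at the quartile the flagged fraction can fall well below 25%; it can also
exceed 25% by at most one rank's worth (< 1/n) due to interpolation.

**Classification metrics.** Sensitivity, specificity, PPV, NPV and accuracy
derive from the 2×2 confusion counts; ratios with zero denominators are
reported as NaN, never as 0.

**Group comparisons.** Score means by outcome are compared with Student's
two-sample t-test (equal variances). Both a vs-survivors mode (standard,
disjoint groups) and a vs-overall mode (deceased vs the entire cohort,
overlapping groups — a convention some validation reports print) are
exposed; the overall mode's p-values are conservative because the deceased
are part of the reference.

**Multiplicity.** All tests are two-sided at α = 0.05 with no
multiple-testing correction; the pairwise DeLong table has C(4,2) = 6
entries and readers should interpret it accordingly.

## Synthetic cohorts

The simulator makes the stack testable without patient data. Each
parameter is drawn independently from a marginal matched to a published
admission profile of hospitalized AECOPD:

* Continuous vitals use truncated normals parameterized by (median, IQR)
  with σ = IQR/1.349 and truncation at plausible physiologic bounds — age
  74 [67, 80] truncated to the reported range [48, 94], heart rate 90
  [78, 103], SpO₂ 92.5 [88, 95], respiratory rate 22 [20, 26], systolic BP
  138 [122, 155].
* Right-skewed labs use truncated lognormals. Spreads not published
  directly are back-solved from printed exceedance prevalences: BUN
  (median 5.5 mmol/L, σ_log 0.25) gives ~2.6% above 8.9 mmol/L; pH
  (7.40, σ ≈ 0.088) gives ~12.7% below 7.30; eosinophils (median 0.08,
  σ_log 1.6) gives ~38.6% below 0.05. Temperature, published only as a
  fever prevalence, uses N(37.0, 0.8²) giving ~11% at ≥ 38 °C.
* Binary findings are Bernoulli at published prevalence (male 53.2%,
  supplemental O₂ 44.4%, altered mental status 7.1%, consolidation 17.9%,
  atrial fibrillation 20.7%).
* Draws are rounded to recording precision (integer vitals, pH to two
  decimals, eosinophils to three), and acidemia/eosinopenia flags are
  derived from the drawn values so both ingestion paths stay consistent.

**Outcome model.** In-hospital death is Bernoulli(expit(α + β·S)) in the
record's true composite score S. The default slope is β = 0.2 per point;
α is calibrated by monotone root-finding (Brent, closed form logit(target)
at β = 0) so the sample-average death probability equals the target
mortality of 2.2%. Thirty-day death (5.4%, forced superset of in-hospital
death) and ICU admission (17.2%) use the same link calibrated to their own
rates.

**Missingness.** Applied after generation, independently per cell at
per-field rates mirroring the published missing-percentage column (pH
27.1%, eosinophils 15.9%, respiratory rate 7.6%, ...). Masking a raw lab
masks its derived flag with it; outcomes are never masked. Binary
prevalences are configured pre-masking, so observed prevalences among
non-missing records match the configuration in expectation.

**Random streams.** A single seed drives everything through per-field
streams keyed by a hash of the field name, so adding or reordering fields
never perturbs other fields' draws, and identical configurations are
bit-reproducible.

**What the simulator does not emulate.** Parameters are independent given
the outcome; real admission parameters are correlated (tachypneic patients
desaturate, acidotic patients are obtunded), and the published joint
structure is unavailable. Consequently simulated AUC levels are properties
of the simulation — useful for verifying monotonicity in β, calibration,
and pipeline integrity — not estimates of any real cohort's discrimination,
and the package makes no claim of reproducing published AUC point
estimates. A configuration hook accepts user-supplied correlation
structure for stress tests.

## Problem sizes in the shipped checks

The test suite and acceptance script run the decomposition identity on
10,000 randomized records, AUC-oracle comparisons on 500 instances of
n ≤ 50, the DeLong-vs-bootstrap variance check on one simulated n = 300
cohort with 2,000 stratified resamples, calibration at n = 100,000, the
β-monotonicity sweep at n = 5,000, and full pipeline runs at the study
scale of n = 314. The variance check uses a 20% event rate rather than
2.2% so both estimators target a well-conditioned quantity (dozens of
events); at a handful of events the bootstrap's small-sample bias alone is
of the same order as the comparison tolerance.

## Known limitations

* The composite's point table is validated structurally and against worked
  examples, not against any external cohort; no claim about real-world
  discrimination follows from green tests here.
* The NEWS consciousness dialect and the DECAF modification (no dyspnea
  item) mean neither score is byte-compatible with registries recording
  full AVPU or eMRCD.
* kNN imputation is single imputation: downstream CIs do not propagate
  imputation uncertainty.
* The vs-overall group comparison is non-standard; prefer vs-survivors for
  inference.
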