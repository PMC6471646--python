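# Methods

This note documents the models, parameters and design choices behind
`peddst`, and what the synthetic-data checks do and do not establish.

## Growth assessment

BMI is computed with Quetelet's equation from weight (kg) and height (cm,
converted to metres at the boundary). Age is real-valued months,
`days / 30.4375` (the mean Gregorian month), with integer-truncated years
exposed alongside; recumbent length is accepted only below 24 months.

The BMI-for-age z-score uses the standard LMS (Box–Cox) transform. Both
branches are evaluated in numerically stable form — `expm1(L·ln r)/(L·S)`
for the general branch and `ln r/S` for |L| ≤ 1e−8 — so the transform is
continuous in L at 0 to within the theoretical Box-Cox gap
|L|·ln²(r)/(2S), which is below 1e−9 near the median at the branch
threshold. The inverse transform (`bmi_from_zscore`) uses the matching
`log1p` form and round-trips to better than 1e−9 across the clinically
relevant parameter range.

L, M and S are linearly interpolated in age, independently per parameter,
which is standard practice for growth references. Percentiles come from
the exact standard normal CDF. Classification is left-closed at the
5/85/95 cutoffs (a percentile of exactly 95 is obese). No z-score capping
is applied; |z| > 5 raises a warning that propagates into the report's
provenance block.

The packaged reference table (`data/lms_synthetic.tsv`) is a **synthetic
fixture**: L = 1, S = 0.18, M linear in age (13.0 kg/m² at birth rising to
≈ 24.9 at 19 y), identical for both sexes. It is smooth, monotone and
convenient for testing, but it is *not* the WHO reference; real tables are
a drop-in TSV.

## CORE risk score

Only the CORE component list and the ≥ 4 threshold are public; the point
assignments live in the validation literature. The score table is
therefore pure configuration: per component, an ordered list of bins
(exact-value matches for sex and smoking; contiguous half-open numeric
intervals for BMI, weight gain and education) mapped to non-negative
points. Validation enforces mutual exclusivity and exhaustiveness, and the
maximum achievable score is reported. The packaged default is a clearly
labelled placeholder. Missing components follow a configurable policy:
`zero_points` (default — contribute 0, surface `n_missing` in the report)
or `refuse`. The score is computed inside the pipeline only for
normal-weight children, matching the pathway; direct calls for other
children are permitted at the library level.

## Energy planning

EER uses the IOM/DRI prediction equations, stored in a versioned constants
file (`data/eer_constants.json`) with a provenance note. Bands: 0–35
months (weight-based equation with month-dependent growth-energy
deposition, 175/56/22/20 kcal/day; boundary months resolve to the younger
bin), 3–8 years and 9–18 years (sex-specific equations with growth energy
20 and 25 kcal/day respectively). Ages between 8 and 9 years use the
younger band's equation; ages above 18 raise an explicit unsupported-band
error rather than extrapolating. Measured weight is used for obese
children (no ideal-weight adjustment), noted here because either choice is
defensible.

The pathway categorises activity by METs (light < 4, moderate 4–7,
vigorous > 7) while the IOM equations expect PA categories; the default
bridge maps light→sedentary (PA 1.00), moderate→low-active (1.13 boys /
1.16 girls), vigorous→active (1.26 / 1.31) and lives in the constants
file, not in code.

The mild-weight-loss goal (obese 6–15 y only) subtracts a configurable
deficit, default 15 % of EER, bounded below by a 1200 kcal/day floor (and
never above the EER). The deficit magnitude is a package default chosen to
be conservative and clinician-overridable; the pathway itself specifies
only the qualitative goal. Macronutrient targets use the 4/9/4 kcal/g
Atwater factors and are validated against the 4–18-year AMDRs
(carbohydrate 45–65 %, fat 25–35 %, protein 10–30 % of energy); the
default prescription split is 55/30/15. Energy is conserved exactly:
Σ grams × factor = target.

Meal plans MP1–MP4 are exchange-based daily templates (ADA exchange
composition per food group) at a reference energy, rescaled proportionally
to the target and rounded to half exchanges (Python banker's rounding
breaks ties deterministically). After rounding, the realised macronutrient
split is re-checked against the AMDR with a 2-percentage-point tolerance;
violations become report warnings, not errors. Plans 2 and 4 carry
machine-checkable composition constraints (max sucrose %kcal, min fibre
g/1000 kcal, max sodium mg/1000 kcal) expressing their fibre-rich /
low-sugar-fat-sodium character.

## Decision tree

The engine is a total function over {age band} × {weight status} × {CORE
risk} × {any disorder} × {any obese parent}. Recommendation placement is
identical in every routed step — (¬dis,¬obP)→R1, (¬dis,obP)→R2,
(dis,¬obP)→R3, (dis,obP)→R4 — with family targeting exactly for R2/R4.
Normal-weight children get no meal plan; overweight children (and obese
2–5-year-olds, which follow the same table) get isocaloric MP1/MP2 with a
maintenance goal; obese 6–15-year-olds get hypocaloric MP3/MP4 with mild
weight loss. Review intervals: normal weight 6 months if a disorder or an
obese parent is present, else 12; overweight/obese 3 months if flagged,
else 6. The "and/or" in the re-evaluation wording is implemented as OR.

Two cells required decisions:

- **Obese 6–15, no disorder, non-obese parents** is not printed anywhere;
  it is filled by symmetry with the overweight table's first cell
  (R1 + MP3, mild loss, review 6) and flagged `inferred_cell=True` in the
  outcome and report provenance.
- **Underweight, over-15, and obese under-2 children** fall outside every
  printed pathway and produce an explicit `refer` outcome rather than an
  error.

Re-evaluation is memoryless: every transition sentence routes purely on
the new BMI percentile, so `reevaluate` delegates to `decide` on the new
state; the previous outcome is kept only for report trajectories. CORE is
re-scored for children who became normal-weight.

The family-targeting and composition-goal invariants (family ⇔ obese
parent; composition goals ⇔ disorder) hold on every routed cell; the
lower-likelihood normal-weight branch is the one principled exception,
since that step issues R1 unconditionally before parents or disorders are
consulted.

## Records, reports and determinism

Records are pydantic models; the strict parent-obesity cutoff is
BMI > 30 kg/m² (exactly 30 is non-obese). Two encodings round-trip to
identical records: family JSON and a flat one-row-per-family CSV
(`float_precision="round_trip"` on read preserves float identity).
Self-reported vs measured parent anthropometry is carried as a source flag
and not processed differently. Bulk loading collects per-record errors by
identifier while returning the valid remainder.

Reports enforce the item-presence invariants at assembly: the risk item
appears iff the child is normal-weight, and the energy/macronutrient/meal-
plan items appear iff a plan was assigned. JSON serialisation is canonical
(sorted keys), so identical inputs and configuration produce byte-identical
output.

## Synthetic cohort

The generator's contract is **moment matching under a fixed seed**, not
distributional fidelity: only means, SEMs and percentages of the emulated
baseline population are known. Continuous variables use truncated normals
whose location is solved (Brent) so the post-truncation mean equals the
target — plain truncation would bias skew-truncated variables like
activity minutes (mean 21.6, SD ≈ 18.5, floor 0) upward by several
minutes. SDs are recovered from printed SEMs as SD = SEM·√65 (the
reference sample size).

Defaults: age 9.7 ± 1.61 y on [6, 12]; status mix 39.3 % overweight /
60.7 % obese; father BMI 28.6, mother BMI 27.3, maternal pre-pregnancy
BMI 24.9 (SDs ≈ 3.2); birth weight 3.2 ± 0.81 kg; activity 21.6 min/day;
maternal education <9 y / 9–12 y / >12 y at 24.6/32.8/42.6 %. Quantities
the emulated population does not report use plausible defaults documented
in `CohortSpec`: maternal smoking 30 %, disorder prevalences 5–15 %,
parental heights 178/165 cm, infant 6-month weight gain 4.0 ± 0.8 kg.

Weight status is generated *through* the classification pathway: a status
is drawn first, then a BMI-for-age percentile uniform on that status's
band (obese capped at 99.9), and BMI follows from the inverse LMS
transform on the same table used for classification — so generated status
and classified status agree by construction, including the degenerate
all-obese spec. Height is age-linked (142.4 cm at the mean age, 6 cm/y
slope, 5.9 cm residual SD) and weight follows from BMI and height. The
synthetic M(age) line was chosen so that the percentile-band mixture
reproduces the 25.1 kg/m² mean BMI in expectation.

What passing cohort tests show: the generator is seed-deterministic,
moment-accurate to 3 standard errors at n = 1000, and every family flows
through the full pipeline. What they do **not** show: anything about real
anthropometric covariance structure, secular trends, measurement error, or
the WHO reference distribution — the fixture table is synthetic and the
variables are drawn (mostly) independently.

A separate stratified generator emits one family per non-referral decision
cell (normal × both risk levels, overweight, obese in both age bands, each
× disorder × parental obesity — 20 cells), used for coverage assertions.

## Trial arithmetic

Only the deterministic arithmetic on printed group means is implemented:
within-group change (follow-up − baseline), between-group difference
(intervention − control), attrition (dropped count and percentage) and its
inverse, enrolment planning (`ceil(n/(1−rate))`). The repeated-measures
ANOVA, adjusted confidence intervals and p-values of the evaluation trial
require participant-level data and are deliberately out of scope.

## Problem sizes

The test suite and acceptance script use n = 1000 cohorts (seconds on one
CPU), 1000-point random grids for the energy-equation oracle check, and
exhaustive enumeration of the 80-state decision space.
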