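# peddst — decision support for paediatric weight management

`peddst` is a Python toolkit for paediatric healthcare professionals and
researchers who need a transparent, testable implementation of a clinical
decision-support pathway for preventing and treating childhood overweight
and obesity. Given a child's visit record (anthropometry, activity level,
clinical-disorder flags), parental data and perinatal history, it produces a
personalised assessment and advice report: weight status, future-obesity
risk, energy and macronutrient prescriptions, a meal-plan assignment, and a
recommendation level with a re-evaluation schedule.

## What it computes

**Level 1 — weight status.** BMI via Quetelet's equation
(weight kg / height m²) is located on a sex- and age-specific reference
distribution using the LMS transform

    z = ((BMI/M)^L − 1) / (L·S),   z → ln(BMI/M)/S as L → 0,

with (L, M, S) linearly interpolated in age from a reference table
(TSV; WHO-style growth references drop in directly). The percentile
Φ(z)·100 is classified with the 5th/85th/95th cutoffs: underweight < 5,
5 ≤ normal < 85, 85 ≤ overweight < 95, obese ≥ 95.

**Level 2 — future-obesity risk.** For normal-weight children, the CORE
(Childhood Obesity Risk Evaluation) index combines perinatal and
socio-demographic factors (maternal pre-pregnancy weight status, smoking
during pregnancy, infant weight gain over the first 6 months, child's sex,
maternal education). A total score ≥ 4 flags a higher likelihood of later
obesity. The component→points table is runtime configuration; the packaged
default is a documented placeholder, not the published coefficients.

**Levels 3–4 — goal and prescriptions.** The weight-management goal
(maintenance, or mild loss for obese 6–15-year-olds) adjusts the IOM
estimated energy requirement, e.g. for boys 9–18 y

    EER = 88.5 − 61.9·age + PA·(26.7·weight + 903·height) + 25,

and the energy target is split over carbohydrate/fat/protein inside the
AMDRs (45–65 / 25–35 / 10–30 % of energy), with grams from the 4/9/4 kcal/g
Atwater factors. Exchange-based meal-plan templates (MP1–MP4) are rescaled
to the target energy.

**Level 5 — decision tree and report.** A fully enumerated five-step
decision table maps (age band, weight status, CORE risk, clinical
disorders, parental obesity) to a recommendation level R1–R4, target
population (child vs family), meal plan, goal and a 3/6/12-month
re-evaluation interval; re-evaluation is memoryless re-classification.
The report (JSON or Markdown) carries the assessment items plus a
provenance block.

A synthetic-cohort generator emulates the baseline population of the
pilot trial that evaluated this style of tool (6–12-year-old overweight or
obese children, ≈ 61 % obese), for end-to-end testing without any external
data.

## Worked example

```bash
dst report --family family.json
```

For a 10.2-year-old boy (52.0 kg, 142.0 cm, moderately active,
dyslipidaemia flagged, father's BMI 31.6 kg/m²), evaluated against the
packaged synthetic reference table, the tool prints:

```
## Weight status
- Category: **obese** (BMI 25.79 kg/m², z = 1.831, percentile 96.64)
- Weight-management goal: mild_loss

## Energy requirement
- EER: 2501.2 kcal/day
- Target (mild_loss): 2126.1 kcal/day

## Macronutrient targets
- carbohydrate: 55.0% of energy, 292.3 g/day
- fat: 30.0% of energy, 70.9 g/day
- protein: 15.0% of energy, 79.7 g/day

## Meal plan
- Plan: MP4 at 2090.5 kcal/day

## Recommendations
- Level: R4 (target: family)
- Re-evaluation in 3 months
```

Reading: the BMI-for-age percentile (96.6) is at or above the 95th cutoff,
so the child is obese; being 6–15 years old with a clinical disorder *and*
an obese parent routes to recommendation 4 (whole-family behavioural
change), the hypocaloric fibre-rich meal plan 4 scaled to the 15 %-deficit
energy target, and the tightest re-evaluation interval. The `dst assess`,
`dst core-score`, `dst decide` and `dst cohort` subcommands expose the
individual stages; all accept the same family JSON/CSV formats.

Note that the packaged LMS table is a synthetic fixture: supply real growth
references with `--lms table.tsv` (header `sex  age_months  L  M  S`) for
clinical use.

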