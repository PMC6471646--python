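# PLACEHOLDER CORE score table.
#
# The published CORE index point assignments are not reproduced here; this
# default only demonstrates the configuration format with plausible bins and
# the standard classification threshold (score >= 4 -> higher likelihood).
# Substitute the validated table to reproduce the published score.
threshold: 4
missing_policy: zero_points
components:
  child_sex:
    - {equals: male, points: 1}
    - {equals: female, points: 0}
  maternal_prepregnancy_bmi:
    - {max: 25.0, points: 0}
    - {min: 25.0, max: 30.0, points: 1}
    - {min: 30.0, points: 2}
  maternal_smoking_pregnancy:
    - {equals: true, points: 1}
    - {equals: false, points: 0}
  weight_gain_0_6mo:
    - {max: 4.5, points: 0}
    - {min: 4.5, points: 2}
  maternal_education_years:
    - {max: 9.0, points: 1}
    - {min: 9.0, points: 0}
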