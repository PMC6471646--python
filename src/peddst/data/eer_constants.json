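{
  "version": "1.0",
  "source_note": "Dietary Reference Intakes energy-requirement prediction equations for infants, children and adolescents (IOM, 2002/2005). Heights in metres, weights in kg, ages in years; growth-energy deposition constants in kcal/day.",
  "infant_0_35mo": {
    "weight_coeff": 89.0,
    "offset": -100.0,
    "growth_energy_by_month": [
      [0, 3, 175.0],
      [3, 6, 56.0],
      [6, 12, 22.0],
      [12, 35, 20.0]
    ]
  },
  "child_3_8y": {
    "growth_energy": 20.0,
    "male": {
      "intercept": 88.5,
      "age_coeff": -61.9,
      "weight_coeff": 26.7,
      "height_coeff": 903.0
    },
    "female": {
      "intercept": 135.3,
      "age_coeff": -30.8,
      "weight_coeff": 10.0,
      "height_coeff": 934.0
    }
  },
  "adolescent_9_18y": {
    "growth_energy": 25.0,
    "male": {
      "intercept": 88.5,
      "age_coeff": -61.9,
      "weight_coeff": 26.7,
      "height_coeff": 903.0
    },
    "female": {
      "intercept": 135.3,
      "age_coeff": -30.8,
      "weight_coeff": 10.0,
      "height_coeff": 934.0
    }
  },
  "pa_coefficients": {
    "male": {"light": 1.0, "moderate": 1.13, "vigorous": 1.26},
    "female": {"light": 1.0, "moderate": 1.16, "vigorous": 1.31}
  }
}
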