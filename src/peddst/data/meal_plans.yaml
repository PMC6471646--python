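# Exchange-based weekly meal-plan templates (daily exchange counts at a
# reference energy).  Plans 1/2 are isocaloric (weight maintenance); plans
# 3/4 are hypocaloric (mild weight loss, obese 6-15 y only).  Plans 2 and 4
# carry machine-checkable composition constraints: rich in dietary fibre and
# complex carbohydrates, with lower simple sugars, total and saturated fat,
# cholesterol and sodium.
plans:
  MP1:
    description: Isocaloric plan for weight maintenance.
    reference_energy: 1645
    exchanges:
      starch: 8
      fruit: 3
      vegetable: 4
      milk_lowfat: 2
      meat_lean: 5
      fat: 4
  MP2:
    description: >-
      Isocaloric plan, fibre-rich and lower in simple sugars, total/saturated
      fat, cholesterol and sodium.
    reference_energy: 1688
    exchanges:
      starch: 8
      fruit: 4
      vegetable: 5
      milk_lowfat: 2
      meat_lean: 5
      fat: 3
    constraints:
      max_pct_kcal_sucrose: 10
      min_fibre_g_per_1000kcal: 14
      max_sodium_mg_per_1000kcal: 1500
  MP3:
    description: Hypocaloric plan for mild weight loss.
    reference_energy: 1464
    exchanges:
      starch: 7
      fruit: 3
      vegetable: 4
      milk_lowfat: 2
      meat_lean: 4
      fat: 3
  MP4:
    description: >-
      Hypocaloric plan, fibre-rich and lower in simple sugars, total/saturated
      fat, cholesterol and sodium.
    reference_energy: 1552
    exchanges:
      starch: 7
      fruit: 4
      vegetable: 5
      milk_lowfat: 2
      meat_lean: 4
      fat: 3
    constraints:
      max_pct_kcal_sucrose: 10
      min_fibre_g_per_1000kcal: 14
      max_sodium_mg_per_1000kcal: 1500
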