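# UK Nutrient Profile Model (2004/05) component threshold tables.
# Every boundary uses a strict inequality: a food earns n points for a
# component when its per-100 g amount strictly exceeds the n-th threshold.
version: "UK NPM 2004/05"
a_points:
  # "A" (penalty) components, 0-10 points each, per 100 g
  energy_kj:  [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
  satfat_g:   [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  sugar_g:    [4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45]
  sodium_mg:  [90, 180, 270, 360, 450, 540, 630, 720, 810, 900]
c_points:
  # "C" (credit) components, 0-5 points each
  # Fruit/vegetable/nut percentage: points jump 0 -> 1 -> 2 -> 5; 3 and 4
  # are unattainable by construction of the model.
  fvn_pct:
    - [40, 1]
    - [60, 2]
    - [80, 5]
  fibre_nsp_g:  [0.7, 1.4, 2.1, 2.8, 3.5]
  fibre_aoac_g: [0.9, 1.9, 2.8, 3.7, 4.7]
  protein_g:    [1.6, 3.2, 4.8, 6.4, 8.0]
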