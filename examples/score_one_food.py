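"""Score one food under the 2004/05 UK Nutrient Profile Model.

A chocolate-hazelnut spread, label values per 100 g. The model awards
penalty (A) points for energy, saturated fat, sugar and sodium and credit
(C) points for fruit/veg/nut content, fibre and protein, then the Nutrient
Profile Index rescales the total: NPI = -2*NPM + 70, healthy at NPI >= 64.
"""

from npiscore import (
    NutrientProfile,
    apply_fvn_ingredient_rule,
    classify_healthfulness,
    compute_npm,
    npm_to_npi,
)

profile = NutrientProfile(
    energy_kj=2252.0,     # 539 kcal
    satfat_g=10.6,
    sugar_g=56.3,
    sodium_mg=40.0,
    fibre_g=3.4,
    protein_g=6.3,
    fibre_basis="AOAC",   # US-label style dietary fibre
    ingredients=("sugar", "palm oil", "hazelnuts", "cocoa", "skim milk"),
)

# fruit/veg/nut % is unknown; "hazelnuts" in the first five ingredients
# triggers the >= 50 % assumption (worth 1 credit point)
profile = apply_fvn_ingredient_rule(profile)

score = compute_npm(profile)
result = npm_to_npi(score.total)

print(f"A-points: energy={score.a_energy} satfat={score.a_satfat} "
      f"sugar={score.a_sugar} sodium={score.a_sodium} (A={score.a_total})")
print(f"C-points: fvn={score.c_fvn} fibre={score.c_fibre} "
      f"protein={score.c_protein} (protein capped: {score.protein_capped})")
print(f"NPM total: {score.total}")
print(f"NPI: {result.npi:.2f}  ->  {classify_healthfulness(result)}")
print()
print("The protein credit is withheld because A >= 11 without maximum "
      "fruit/veg/nut points; NPI below 64 classifies the spread unhealthy.")
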