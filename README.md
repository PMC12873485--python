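# npiscore

Nutrient-profile scoring and descriptive analysis for food-marketing
content studies.

Public-health researchers auditing what food and beverage products appear
in marketing content (for example, social-media influencer videos) need a
reproducible way to (1) judge the healthfulness of each featured food, (2)
classify every product into a category taxonomy, and (3) summarize a coded
corpus into the usual descriptive table. `npiscore` packages that pipeline:

- **NPM scoring** — the 2004/05 UK Nutrient Profile Model. Per 100 g, a
  food earns penalty points A ∈ 0–10 per component for energy (kJ),
  saturated fat (g), total sugar (g) and sodium (mg), and credit points
  C ∈ 0–5 per component for fruit/vegetable/nut content (%), fibre (g, NSP
  or AOAC basis) and protein (g), each read from strict-inequality
  threshold tables. The total is

  `NPM = A − C_fvn − C_fibre − C_protein`,

  with the protein credit withheld when A ≥ 11 unless the food earns the
  maximum 5 fruit/veg/nut points.
- **NPI conversion** — the Nutrient Profile Index `NPI = −2·NPM + 70` on a
  nominal 1–100 scale (higher = healthier). `NPI ≥ 64` — the image of the
  UK child-advertising cut-off `NPM ≤ 3` — classifies a food healthy.
- **Product catalog** — a category taxonomy (food groups plus
  processed/packaged, prepared and restaurant categories; Rudd Center
  children's-drinks categories plus alcoholic beverages and plain water for
  drinks), keyword-rule classification, and nutrition-data resolution:
  branded label → restaurant report NPI → top-five menu average → generic
  reference, with explicit omission of foods lacking nutrition data.
  Beverages and supplements are categorized but never NPI-scored.
- **Summary layer** — counts and half-up-rounded percentages, category
  frequency tables, and NPI mean/SD and percent-unhealthy stratified by
  brand status.
- **Synthetic corpus generator** — draws study-shaped corpora (product
  prevalence, type split, brand share, category mixes, brand-stratified NPM
  distributions calibrated to target NPI moments) so the whole pipeline is
  testable end to end.

## Worked example

```python
from npiscore import (NutrientProfile, apply_fvn_ingredient_rule,
                      compute_npm, npm_to_npi, classify_healthfulness)

profile = NutrientProfile(
    energy_kj=2252.0, satfat_g=10.6, sugar_g=56.3, sodium_mg=40.0,
    fibre_g=3.4, protein_g=6.3, fibre_basis="AOAC",
    ingredients=("sugar", "palm oil", "hazelnuts", "cocoa", "skim milk"),
)
profile = apply_fvn_ingredient_rule(profile)   # nuts in first five -> fvn 50 %
score = compute_npm(profile)
result = npm_to_npi(score.total)
print(score.total, result.npi, classify_healthfulness(result))
```

Running `python examples/score_one_food.py` prints:

```
A-points: energy=6 satfat=10 sugar=10 sodium=0 (A=26)
C-points: fvn=1 fibre=3 protein=3 (protein capped: True)
NPM total: 22
NPI: 26.00  ->  unhealthy
```

The spread's energy, saturated fat and sugar accumulate 26 penalty points;
because A ≥ 11 without maximum fruit/veg/nut credit, the protein credit is
withheld, leaving NPM 22, i.e. NPI 26 — far below the healthy cut-off of
64. The other examples (`examples/classify_products.py`,
`examples/simulate_and_summarize.py`) walk through the catalog pipeline
and a full synthetic-corpus summary; `examples/simulate_and_summarize.py`
prints the study-style table with stratified NPI means (branded foods
scoring systematically lower than unbranded ones).

A thin CLI wraps the same pipeline:

```sh
npiscore simulate --out corpus --n-videos 8871 --seed 7
npiscore score --products corpus/products.csv \
    --branded corpus/branded_nutrition.csv \
    --generic corpus/generic_nutrition.csv \
    --restaurant-report corpus/restaurant_report.csv \
    --out scored.csv
npiscore summarize --scored scored.csv --n-videos 8871 --out summary.json
```

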