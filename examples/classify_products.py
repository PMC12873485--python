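"""Run a handful of products through the full categorize/resolve/score pipeline.

Builds the nutrition lookup tables in memory (a branded label, a generic
reference entry and a restaurant NPI report), then categorizes each product
by keyword rules, routes it to its nutrition pathway and scores the foods.
Beverages keep a category only - the NPM is not reliable for drinks.
"""

from npiscore import NutritionTables, ProductRecord, npm_to_profile, run_pipeline

tables = NutritionTables()
tables.branded["snack-01"] = npm_to_profile(18)       # an indulgent snack label
tables.generic["fruit salad"] = npm_to_profile(-8)    # reference-database entry
tables.restaurant_report["BurgerTown"] = 38.0         # pre-extracted report NPI

records = [
    ProductRecord("snack-01", "v1", "chocolate chip cookie snack", "food", branded=True),
    ProductRecord("gen-01", "v2", "Fruit Salad", "food", branded=False),
    ProductRecord("rest-01", "v3", "BurgerTown", "food", branded=True, restaurant=True),
    ProductRecord("mys-01", "v4", "grandma's secret pie", "food", branded=False),
    ProductRecord("bev-01", "v5", "craft IPA beer", "beverage", branded=True),
]

run_pipeline(records, tables)

for r in records:
    if r.npi is not None:
        outcome = f"NPI {r.npi.npi:.1f} ({'healthy' if r.npi.healthy else 'unhealthy'})"
    elif r.omission_reason:
        outcome = f"omitted: {r.omission_reason}"
    else:
        outcome = "not scored (beverage/supplement)"
    print(f"{r.name:28s} {r.category:22s} {r.nutrition_source:18s} {outcome}")

print()
print("Each food exits scored or with an explicit omission reason; the "
      "restaurant uses its report NPI, and the beverage is categorised only.")
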