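# Methods

## The scoring model

`npiscore` implements the 2004/05 UK Nutrient Profile Model (NPM), the
scoring scheme developed to identify foods whose advertising to children
is restricted in the UK, and the Nutrient Profile Index (NPI) rescaling
used in food-marketing research. All amounts are per 100 g of food as
consumed.

Penalty ("A") components, 0–10 points each, one point per threshold
strictly exceeded:

| component | unit | thresholds |
|---|---|---|
| energy | kJ | 335·n (n = 1..10) |
| saturated fat | g | 1·n |
| total sugar | g | 4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45 |
| sodium | mg | 90·n |

Credit ("C") components, 0–5 points each:

| component | unit | thresholds |
|---|---|---|
| fruit/veg/nut | % | >40 → 1, >60 → 2, >80 → 5 (3, 4 unattainable) |
| fibre (NSP) | g | 0.7·n (n = 1..5) |
| fibre (AOAC) | g | 0.9, 1.9, 2.8, 3.7, 4.7 |
| protein | g | 1.6·n |

`NPM = A − C_fvn − C_fibre − C_protein`, integer in [−15, 40]. **Protein
cap:** the protein credit is withheld whenever A ≥ 11 and the food does
not earn the maximum 5 fruit/veg/nut points. Every comparison is a strict
inequality — an amount exactly at a threshold does not earn the point.

`NPI = −2·NPM + 70`, reported on the nominal 1–100 scale (higher =
healthier). A food is **healthy** iff its unclamped NPI is ≥ 64,
equivalently NPM ≤ 3, the UK child-advertising cut-off. The index is
clamped to [1, 100] for reporting (NPM ≥ 35 maps below 1 raw), but the
raw value is retained so the cut-off equivalence stays exact; whether the
original protocol clamped sub-1 values is not documented, so both values
are carried.

Unit conventions: energy may be supplied in kcal (converted at
4.184 kJ/kcal); sodium may be derived from salt at 400 mg sodium per g
salt; per-serving label values are rescaled by 100/serving-weight. The
default fibre basis is AOAC because US nutrition labels report AOAC-style
dietary fibre; NSP thresholds are available by flag. Missing credit
components score 0 (credits only improve a score), while a missing
penalty component makes the food unscorable and it is omitted from
analysis with an explicit reason.

**Fruit/veg/nut assumption.** When the fruit/veg/nut fraction is unknown,
a food whose first five ingredients include a fruit, vegetable or nut
(editable lexicon, `data/fvn_lexicon.yaml`) is assumed to contain at least
50 % — the stated lower bound, deliberately conservative: it yields 1
credit point, not 2 or 5. The lexicon avoids terms that usually denote
derived fats/syrups in ingredient lists (olive, corn, bean) to limit
false positives from "olive oil" or "corn syrup".

## Catalog and nutrition resolution

Products are classified by ordered keyword rules into a fixed taxonomy
(`data/categories.yaml`): foods into food groups plus processed/packaged
(breakfast cereals, packaged snacks, condiments and cooking staples),
prepared (mixed dishes, desserts), restaurant, fruits-and-vegetables,
protein and other; beverages into the Rudd Center children's-drinks
categories extended with alcoholic beverages and plain water, with
sweetened and unsweetened coffee/tea combined. Restaurant-origin foods
always take the restaurant category; unmatched items fall to the
type-appropriate "other" bucket with a warning, never a failure.
Categorization is a deterministic total function.

Foods resolve to a nutrition pathway in a fixed order: branded-label
table (keyed by product id) → restaurant report (pre-extracted NPI per
restaurant name) → restaurant top-five menu average → generic reference
table (keyed by lowercased name). Restaurant averaging takes the
arithmetic mean of the (up to five) items' NPI values and compares the
mean against 64; averaging on the NPI rather than NPM scale is the
package's reading of the protocol — the two give identical means up to
the affine map, but the healthy verdict of a mean need not equal the
majority verdict of per-item classifications. Foods matching no table are
omitted with the reason recorded; `scored + omitted = foods` always
holds. Beverages and dietary supplements are categorized but never
scored: the NPM was not designed for drinks, and supplements fall outside
its scope. One product per video is enforced at ingestion.

## Summary layer

Percentages are computed from the layer's own numerators and denominators
and rounded half-up to 1 decimal (e.g. 1360/8871 → 15.3); NPI means/SDs
to 2 decimals with the sample (n−1) SD. The unhealthy share is computed
over scored foods only, with NPI exactly 64 counting healthy. Category
tables sort by descending count, ties alphabetical, and carry their
stratum denominators; branded + unbranded counts are additive per row. A
consistency field reports the gap between the pooled NPI mean and the
stratum-weighted mean (zero up to rounding). Published food-category
percentages in this literature are not always consistent with their
stated denominators; this layer never copies percentages, it recomputes
them.

## Synthetic corpus generator

The generator emulates a coded influencer-video corpus. Defaults are the
study conditions of the motivating dataset: 8871 videos; product
probability 1360/8871 (15.3 %); type split 755/580/25 over
food/beverage/supplement (55.5/42.6/1.8 %); branded share 0.476;
per-brand-status category mixes anchored at the reported count/percent
cells. The anchored food cells imply ≈244 branded (95 packaged snacks at
38.9 %) and ≈527 unbranded (107 desserts at 20.3 %) foods; the remaining
mass is spread over the unreported categories so each mix sums to 1.
Omission probabilities back out the reported 86 unscorable foods split
81 unbranded / 5 branded: with the single 0.476 branded share the
expected food strata are ≈359/396, giving 5/359 ≈ 0.014 and
81/396 ≈ 0.205, i.e. ≈11.4 % of foods omitted in expectation.

Food healthfulness is drawn on the NPM scale: per brand stratum, an
integer NPM total from a **discretized truncated normal** on [−15, 40]
(mass of (k−½, k+½] under N(μ, σ²), renormalized). The (μ, σ) defaults
are solved by exact moment matching on that pmf so the *realized*
distribution hits the target NPI moments — branded (49.58, 17.80),
unbranded (57.61, 20.52) — rather than the untruncated normal hitting
them; the solve is deterministic (no sampling involved). Each drawn total
is inverted constructively into a `NutrientProfile` that scores back to
exactly that total: non-negative totals from A-points alone (credits in
their zero bins), negative totals from credits alone using fvn = 5 to
reach beyond 10 (3 and 4 fvn points do not exist); amounts are jittered
uniformly within their threshold bins, strictly inside the boundaries, so
the round-trip is exact by construction and property-tested over all 56
integer totals. Scorable restaurant-category foods are emitted as
pre-extracted report NPIs to exercise that pathway; unscorable foods get
no table entry at all, so the pipeline omits them organically.

A single seed drives one `numpy` generator for all draws; fixed seed ⇒
byte-identical corpus, scores and summaries.

What the generator does *not* emulate: engagement metrics, influencer
identity, posting time, sponsorship disclosure, correlations between
category and healthfulness within a stratum (NPM totals are drawn
independently of category), and real label-nutrient correlation structure
(profiles are constructed from target totals, not sampled from food
composition data). Passing recovery tests therefore demonstrates that the
pipeline measures what the generator encodes — not that real corpora
share the generator's independence assumptions.

## Problem sizes and numerical choices

The recovery check runs a 50 000-video corpus (≈7 600 products, ≈3 700
scored foods) end to end, large enough that 3-standard-error bounds on
shares and stratum NPI means are a fraction of a percentage point/NPI
point; the calibrated strata are additionally required to land within 1
NPI point of their targets. Category mixes are tested with an aggregate
chi-square goodness-of-fit per type × stratum (per-cell z-tests across
~36 cells would reject some seed by chance alone). The brute-force oracle
grid uses >10 000 profiles with every component placed ±0.05 around each
of its thresholds, the regime where an off-by-one or non-strict
comparison would surface. Determinism is asserted byte-for-byte on all
written artifacts at a fixed seed.

## Known limitations

- Keyword categorization is a transparent stand-in for human coding;
  precision on free-text product names depends entirely on the editable
  rule lists.
- The FVN first-five-ingredients rule is binary at 50 %; single-ingredient
  produce gets 1 credit point, not the 5 a human coder might assign.
- The NPM threshold tables are the 2004/05 model; later revisions (e.g.
  the 2018 consultation model) are deliberately out of scope, but
  alternative tables can be loaded from YAML.
- Restaurant top-five item *selection* is an input responsibility (rows
  flagged as top-5); the package averages what it is given.
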