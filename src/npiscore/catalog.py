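"""Product records, category taxonomy and nutrition-data resolution.

Each featured product (one per video) is classified into a fixed taxonomy:
foods into food groups extended with processed/packaged, prepared and
restaurant categories; beverages into the Rudd Center children's-drinks
categories extended with alcoholic beverages and plain water (sweetened and
unsweetened coffee/tea combined). Foods are then routed to a nutrition-data
pathway — a branded-label table, a pre-extracted restaurant NPI report, a
top-five menu-item average, or a generic reference table — and scored, or
excused with an explicit omission reason. Beverages and supplements are
categorised only: the NPM is not reliable for beverages, so they never
receive an NPI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from statistics import fmean

import yaml

from .errors import ConfigurationError, SchemaError, UnscorableError
from .profiles import HEALTHY_NPI_CUTOFF, NPIResult, NPMScore, NutrientProfile
from .scoring import apply_fvn_ingredient_rule, compute_npm, npm_to_npi
from .thresholds import ThresholdTables

logger = logging.getLogger(__name__)

PRODUCT_TYPES = ("food", "beverage", "supplement")

#: Nutrition-data pathways, in resolution order for foods.
NUTRITION_SOURCES = ("branded_label", "restaurant_report", "restaurant_top5",
                     "generic_reference", "none")

RESTAURANT_CATEGORY = "fast-food/restaurant"
OMISSION_NO_DATA = "no nutrition information"


@dataclass
class ProductRecord:
    """One featured product: identity, classification and scoring outcome."""

    product_id: str
    video_id: str
    name: str
    product_type: str
    branded: bool
    restaurant: bool = False
    top5: bool = False
    category: str | None = None
    nutrition_source: str | None = None
    profile: NutrientProfile | None = None
    npm: NPMScore | None = None
    npi: NPIResult | None = None
    omission_reason: str | None = None

    def __post_init__(self) -> None:
        if self.product_type not in PRODUCT_TYPES:
            raise SchemaError(
                f"product_type must be one of {PRODUCT_TYPES}, got {self.product_type!r}")


@dataclass(frozen=True)
class CategoryTaxonomy:
    food_categories: tuple[str, ...]
    beverage_categories: tuple[str, ...]
    supplement_categories: tuple[str, ...] = ("dietary supplement",)

    def __post_init__(self) -> None:
        for labels in (self.food_categories, self.beverage_categories,
                       self.supplement_categories):
            if not labels:
                raise ConfigurationError("taxonomy has an empty category list")
            if len(set(labels)) != len(labels):
                raise ConfigurationError("taxonomy labels must be unique")

    def for_type(self, product_type: str) -> tuple[str, ...]:
        return {
            "food": self.food_categories,
            "beverage": self.beverage_categories,
            "supplement": self.supplement_categories,
        }[product_type]

    def other_bucket(self, product_type: str) -> str:
        # Last label of each list is the catch-all by convention.
        return self.for_type(product_type)[-1]


@dataclass(frozen=True)
class CategoryRules:
    """Ordered keyword rules per product type; first match wins."""

    rules: dict[str, tuple[tuple[str, tuple[str, ...]], ...]]

    def match(self, product_type: str, name: str) -> str | None:
        lowered = name.lower()
        for category, keywords in self.rules.get(product_type, ()):
            if any(kw in lowered for kw in keywords):
                return category
        return None


def load_taxonomy(path: str | Path | None = None) -> tuple[CategoryTaxonomy, CategoryRules]:
    """Load the taxonomy and keyword rules from YAML (packaged defaults)."""
    if path is None:
        text = resources.files("npiscore.data").joinpath("categories.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    try:
        tax = raw["taxonomy"]
        taxonomy = CategoryTaxonomy(
            food_categories=tuple(tax["food"]),
            beverage_categories=tuple(tax["beverage"]),
            supplement_categories=tuple(tax.get("supplement", ["dietary supplement"])),
        )
        rules = CategoryRules(rules={
            ptype: tuple((r["category"], tuple(str(k).lower() for k in r["keywords"]))
                         for r in rule_list)
            for ptype, rule_list in raw.get("rules", {}).items()
        })
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed taxonomy file: {exc}") from exc
    for ptype, rule_list in rules.rules.items():
        known = set(taxonomy.for_type(ptype))
        for category, _ in rule_list:
            if category not in known:
                raise ConfigurationError(
                    f"rule category {category!r} not in {ptype} taxonomy")
    return taxonomy, rules


def categorize_product(record: ProductRecord, taxonomy: CategoryTaxonomy,
                       rules: CategoryRules) -> ProductRecord:
    """Assign a taxonomy category; deterministic, total (falls back to 'other').

    Restaurant-origin foods always map to the restaurant category before
    any keyword rule runs. An explicit, taxonomy-valid category supplied
    upstream is kept as-is.
    """
    if record.category is not None:
        if record.category not in taxonomy.for_type(record.product_type):
            raise ConfigurationError(
                f"explicit category {record.category!r} not in taxonomy "
                f"for {record.product_type}")
        return record
    if record.product_type == "food" and record.restaurant:
        record.category = RESTAURANT_CATEGORY
        return record
    matched = rules.match(record.product_type, record.name)
    if matched is None:
        record.category = taxonomy.other_bucket(record.product_type)
        logger.warning("no category rule matched %r (%s); using %r",
                       record.name, record.product_type, record.category)
    else:
        record.category = matched
    return record


@dataclass
class NutritionTables:
    """Local nutrition lookup tables replacing the study's live sources.

    ``branded`` is keyed by product_id (label data); ``generic`` by
    lowercased product name (reference-database data); ``restaurant_report``
    maps a restaurant name to a pre-extracted NPI value;
    ``restaurant_menu`` maps a restaurant name to its top menu items'
    profiles for the top-five averaging pathway.
    """

    branded: dict[str, NutrientProfile] = field(default_factory=dict)
    generic: dict[str, NutrientProfile] = field(default_factory=dict)
    restaurant_report: dict[str, float] = field(default_factory=dict)
    restaurant_menu: dict[str, list[NutrientProfile]] = field(default_factory=dict)
    #: keys (product_id or lowercased name) of rows present in a source
    #: table but unusable, mapped to the reason (e.g. missing serving weight)
    problems: dict[str, str] = field(default_factory=dict)


def restaurant_top5_score(items: list[NutrientProfile],
                          tables: ThresholdTables | None = None) -> NPIResult:
    """Average the NPI of a restaurant's top (up to five) menu items.

    The aggregate NPI is the arithmetic mean of the items' NPI values and
    the healthy flag compares that mean against the 64 cut-off. Fewer than
    five items are averaged with a warning; zero items are unscorable.
    """
    if not items:
        raise UnscorableError("no scorable menu items for restaurant averaging")
    if len(items) != 5:
        logger.warning("restaurant averaging over %d items (expected 5)", len(items))
    npis = [npm_to_npi(compute_npm(p, tables).total).npi for p in items]
    mean_npi = fmean(npis)
    return NPIResult(npi=mean_npi, npi_raw=mean_npi,
                     healthy=mean_npi >= HEALTHY_NPI_CUTOFF)


def _score_profile(record: ProductRecord, profile: NutrientProfile,
                   tables: ThresholdTables | None,
                   fvn_lexicon: frozenset[str] | None) -> None:
    profile = apply_fvn_ingredient_rule(profile, fvn_lexicon)
    record.profile = profile
    record.npm = compute_npm(profile, tables)
    record.npi = npm_to_npi(record.npm.total)


def resolve_nutrition_source(record: ProductRecord, tables: NutritionTables,
                             thresholds: ThresholdTables | None = None,
                             fvn_lexicon: frozenset[str] | None = None,
                             ) -> ProductRecord:
    """Route a categorized food to its nutrition pathway and score it.

    Pathway order: branded label -> restaurant report -> restaurant
    top-five average -> generic reference; a food matching none is omitted
    from the NPI analysis with an explicit reason. Beverages and
    supplements keep their category and are never scored.
    """
    if record.category is None:
        raise ConfigurationError("record must be categorized before resolution")
    if record.product_type != "food":
        record.nutrition_source = "none"
        return record

    is_restaurant = record.restaurant or record.category == RESTAURANT_CATEGORY
    try:
        if is_restaurant:
            key = record.name
            if key in tables.restaurant_report:
                record.nutrition_source = "restaurant_report"
                record.npi = NPIResult.from_raw(float(tables.restaurant_report[key]))
            elif key in tables.restaurant_menu:
                record.nutrition_source = "restaurant_top5"
                record.npi = restaurant_top5_score(tables.restaurant_menu[key], thresholds)
            else:
                record.nutrition_source = "none"
                record.omission_reason = OMISSION_NO_DATA
        elif record.branded and record.product_id in tables.branded:
            record.nutrition_source = "branded_label"
            _score_profile(record, tables.branded[record.product_id],
                           thresholds, fvn_lexicon)
        elif record.name.lower() in tables.generic:
            record.nutrition_source = "generic_reference"
            _score_profile(record, tables.generic[record.name.lower()],
                           thresholds, fvn_lexicon)
        else:
            record.nutrition_source = "none"
            record.omission_reason = (
                tables.problems.get(record.product_id)
                or tables.problems.get(record.name.lower())
                or OMISSION_NO_DATA)
    except UnscorableError as exc:
        record.nutrition_source = record.nutrition_source or "none"
        record.npi = None
        record.omission_reason = str(exc)
    return record


def validate_one_product_per_video(records: list[ProductRecord]) -> None:
    """Reject inputs with more than one product row per video."""
    seen: dict[str, str] = {}
    for i, rec in enumerate(records):
        if rec.video_id in seen:
            raise SchemaError(
                f"video {rec.video_id!r} has multiple product rows "
                f"({seen[rec.video_id]!r} and {rec.product_id!r}); "
                "only one product per video is allowed", row=i + 1)
        seen[rec.video_id] = rec.product_id


def run_pipeline(records: list[ProductRecord], tables: NutritionTables,
                 taxonomy: CategoryTaxonomy | None = None,
                 rules: CategoryRules | None = None,
                 thresholds: ThresholdTables | None = None,
                 fvn_lexicon: frozenset[str] | None = None,
                 ) -> list[ProductRecord]:
    """Categorize, resolve and score every record (in place; returns records).

    Every food exits scored or with an omission reason; beverages and
    supplements exit categorized. Deterministic: same inputs and config
    give identical outputs.
    """
    if taxonomy is None or rules is None:
        default_tax, default_rules = load_taxonomy()
        taxonomy = taxonomy or default_tax
        rules = rules or default_rules
    validate_one_product_per_video(records)
    for record in records:
        categorize_product(record, taxonomy, rules)
        resolve_nutrition_source(record, tables, thresholds, fvn_lexicon)
    return records
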