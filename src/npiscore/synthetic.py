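"""Synthetic study-corpus generator.

The study's raw data (screen-recorded videos) cannot be redistributed, so
this module generates corpora with the same statistical structure: per
video, a Bernoulli product indicator; per product, a type (food, beverage,
supplement), a brand status, a category drawn from brand-specific mixes,
and — for foods — an NPM total drawn from a brand-stratified discretized
truncated normal on the integer support [-15, 40], inverted constructively
into a per-100 g :class:`NutrientProfile` that scores back to exactly that
total. Unscorable foods (no nutrition information available) are emitted
without table entries so the pipeline omits them, reproducing the study's
missing-data pattern.

Default parameters are the study's printed conditions: 8871 videos, 15.3 %
featuring a product, a 55.5/42.6/1.8 food/beverage/supplement split,
47.6 % branded, brand-specific category mixes backed out of the reported
counts, and NPM distributions calibrated so branded/unbranded NPI means
and SDs hit (49.58, 17.80) and (57.61, 20.52).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.optimize import fsolve
from scipy.stats import norm

from .catalog import RESTAURANT_CATEGORY, NutritionTables, ProductRecord
from .errors import ConfigurationError, NpiScoreError
from .profiles import NutrientProfile
from .scoring import compute_npm
from .thresholds import ThresholdTables, default_thresholds

NPM_MIN, NPM_MAX = -15, 40
NPM_SUPPORT = np.arange(NPM_MIN, NPM_MAX + 1)

PRODUCT_TYPES = ("food", "beverage", "supplement")

# Brand-specific category mixes. Anchor cells are the study's reported
# count/percent pairs; the remainder is spread over the unreported
# categories so each mix sums to 1 (arithmetic in docs/methods.md).
FOOD_MIX_BRANDED = {
    "packaged snacks": 0.389,
    "fast-food/restaurant": 0.332,
    "condiments and cooking staples": 0.070,
    "desserts": 0.050,
    "breakfast cereals": 0.040,
    "mixed dishes": 0.040,
    "fruits and vegetables": 0.020,
    "protein": 0.030,
    "other food": 0.029,
}
FOOD_MIX_UNBRANDED = {
    "desserts": 0.203,
    "fruits and vegetables": 0.180,
    "protein": 0.139,
    "packaged snacks": 0.127,
    "mixed dishes": 0.120,
    "fast-food/restaurant": 0.066,
    "breakfast cereals": 0.040,
    "condiments and cooking staples": 0.040,
    "other food": 0.085,
}
BEVERAGE_MIX_BRANDED = {
    "energy drinks": 0.389,
    "alcoholic beverages": 0.213,
    "coffee/tea": 0.130,
    "fruit drinks": 0.070,
    "flavored water": 0.050,
    "sweetened milk": 0.030,
    "100% juice": 0.030,
    "plain water": 0.018,
    "other beverage": 0.070,
}
BEVERAGE_MIX_UNBRANDED = {
    "alcoholic beverages": 0.365,
    "other beverage": 0.255,
    "coffee/tea": 0.150,
    "plain water": 0.080,
    "fruit drinks": 0.050,
    "sweetened milk": 0.035,
    "100% juice": 0.030,
    "flavored water": 0.030,
    "energy drinks": 0.005,
}

#: Published brand-stratified NPI moments used to calibrate the defaults.
TARGET_NPI = {"branded": (49.58, 17.80), "unbranded": (57.61, 20.52)}


@dataclass(frozen=True)
class NpmDistribution:
    """Discretized truncated normal over integer NPM totals in [-15, 40].

    ``mu``/``sigma`` parameterize the underlying normal; the pmf places
    integer k at the normal mass of (k - 1/2, k + 1/2], renormalized over
    the support.
    """

    mu: float
    sigma: float

    def pmf(self) -> np.ndarray:
        edges = np.arange(NPM_MIN - 0.5, NPM_MAX + 1.0)
        cdf = norm.cdf(edges, loc=self.mu, scale=self.sigma)
        p = np.diff(cdf)
        total = p.sum()
        if total <= 0:
            raise ConfigurationError("NPM distribution has no mass on [-15, 40]")
        return p / total

    def moments(self) -> tuple[float, float]:
        p = self.pmf()
        mean = float(NPM_SUPPORT @ p)
        sd = float(np.sqrt(((NPM_SUPPORT - mean) ** 2) @ p))
        return mean, sd

    def npi_moments(self) -> tuple[float, float]:
        mean, sd = self.moments()
        return -2.0 * mean + 70.0, 2.0 * sd


def calibrate_npm_dist(target_npi_mean: float, target_npi_sd: float) -> NpmDistribution:
    """Solve for (mu, sigma) whose discretized truncated pmf hits NPI targets.

    Moment matching is exact on the pmf (no sampling): the solver adjusts
    the underlying normal so the *realized* distribution moments — after
    discretization and truncation — equal the targets on the NPM scale
    (NPM mean = (70 - NPI mean)/2, NPM sd = NPI sd / 2).
    """
    target_mean = (70.0 - target_npi_mean) / 2.0
    target_sd = target_npi_sd / 2.0

    def residual(x: np.ndarray) -> list[float]:
        mean, sd = NpmDistribution(mu=float(x[0]), sigma=abs(float(x[1]))).moments()
        return [mean - target_mean, sd - target_sd]

    solution = fsolve(residual, x0=[target_mean, target_sd], full_output=False)
    dist = NpmDistribution(mu=float(solution[0]), sigma=abs(float(solution[1])))
    mean, sd = dist.moments()
    if abs(mean - target_mean) > 1e-6 or abs(sd - target_sd) > 1e-6:
        raise ConfigurationError(
            f"NPM calibration failed for targets ({target_npi_mean}, {target_npi_sd})")
    return dist


def _check_simplex(name: str, probs: dict[str, float] | tuple[float, ...]) -> None:
    values = list(probs.values()) if isinstance(probs, dict) else list(probs)
    if any(p < 0 or p > 1 for p in values):
        raise ConfigurationError(f"{name}: probabilities must lie in [0, 1]")
    if abs(sum(values) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name}: probabilities sum to {sum(values)}, not 1")


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic corpus.

    Defaults reproduce the published corpus structure; they are conditions,
    not tuning knobs. ``npm_dist`` defaults to the calibrated distributions
    targeting the printed branded/unbranded NPI moments.
    """

    n_videos: int = 8871
    p_product: float = 1360 / 8871
    type_probs: dict[str, float] = field(default_factory=lambda: {
        "food": 755 / 1360, "beverage": 580 / 1360, "supplement": 25 / 1360})
    p_branded: float = 0.476
    food_category_mix: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "branded": dict(FOOD_MIX_BRANDED), "unbranded": dict(FOOD_MIX_UNBRANDED)})
    beverage_category_mix: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "branded": dict(BEVERAGE_MIX_BRANDED), "unbranded": dict(BEVERAGE_MIX_UNBRANDED)})
    npm_dist: dict[str, NpmDistribution] | None = None
    # Omission probabilities back out the published 86 omitted foods
    # (81 unbranded, 5 branded) under the 47.6 % branded share.
    p_unscorable: dict[str, float] = field(default_factory=lambda: {
        "branded": 5 / 359, "unbranded": 81 / 396})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.npm_dist is None:
            self.npm_dist = {stratum: calibrate_npm_dist(*targets)
                             for stratum, targets in TARGET_NPI.items()}

    def validate(self) -> None:
        if self.n_videos < 0:
            raise ConfigurationError("n_videos must be >= 0")
        for name, p in (("p_product", self.p_product), ("p_branded", self.p_branded),
                        *((f"p_unscorable[{k}]", v) for k, v in self.p_unscorable.items())):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        _check_simplex("type_probs", self.type_probs)
        if set(self.type_probs) != set(PRODUCT_TYPES):
            raise ConfigurationError(f"type_probs keys must be {PRODUCT_TYPES}")
        for label, mixes in (("food_category_mix", self.food_category_mix),
                             ("beverage_category_mix", self.beverage_category_mix)):
            for stratum, mix in mixes.items():
                _check_simplex(f"{label}[{stratum}]", mix)


def _amount_in_bin(thresholds: tuple[float, ...], points: int,
                   rng: np.random.Generator | None) -> float:
    """Amount scoring exactly ``points`` under a strict-> threshold table.

    Deterministic (bin midpoint) without an rng; otherwise uniform inside
    the bin, kept strictly above the lower edge.
    """
    if points == 0:
        hi = thresholds[0]
        return hi * (float(rng.uniform(0.0, 1.0)) if rng is not None else 0.5)
    if points == len(thresholds):
        lo = thresholds[-1]
        hi = lo * 1.5 + 1.0
    else:
        lo, hi = thresholds[points - 1], thresholds[points]
    u = float(rng.uniform(0.05, 1.0)) if rng is not None else 0.5
    return lo + (hi - lo) * u


_FVN_BINS = {0: (0.0, 40.0), 1: (40.0, 60.0), 2: (60.0, 80.0), 5: (80.0, 100.0)}


def _fvn_amount(points: int, rng: np.random.Generator | None) -> float:
    lo, hi = _FVN_BINS[points]
    if points == 0:
        return hi * (float(rng.uniform(0.0, 1.0)) if rng is not None else 0.0)
    u = float(rng.uniform(0.05, 1.0)) if rng is not None else 0.5
    return lo + (hi - lo) * u


def npm_to_profile(target_npm: int, tables: ThresholdTables | None = None,
                   rng: np.random.Generator | None = None) -> NutrientProfile:
    """Construct a profile whose NPM total equals ``target_npm`` exactly.

    Non-negative targets are built from A-points alone (credits held in
    their zero bins); negative targets from C-points alone, using fruit/
    veg/nut = 5 to reach credits beyond 10 (3 and 4 fruit/veg/nut points do
    not exist). Amounts are placed strictly inside the correct threshold
    bins, so ``compute_npm`` round-trips exactly; with an rng, amounts are
    jittered within their bins without changing any point allocation.
    """
    if not NPM_MIN <= target_npm <= NPM_MAX:
        raise ConfigurationError(f"target NPM must be in [{NPM_MIN}, {NPM_MAX}]")
    tables = tables or default_thresholds()

    a_alloc = [0, 0, 0, 0]
    c_alloc = {"fvn": 0, "fibre": 0, "protein": 0}
    if target_npm >= 0:
        remaining = int(target_npm)
        for i in range(4):
            a_alloc[i] = min(10, remaining)
            remaining -= a_alloc[i]
    else:
        credits = -int(target_npm)
        if credits > 10:
            c_alloc["fvn"] = 5
            credits -= 5
        c_alloc["protein"] = min(5, credits)
        c_alloc["fibre"] = credits - c_alloc["protein"]

    profile = NutrientProfile(
        energy_kj=_amount_in_bin(tables.a_tables["energy"], a_alloc[0], rng),
        satfat_g=_amount_in_bin(tables.a_tables["satfat"], a_alloc[1], rng),
        sugar_g=_amount_in_bin(tables.a_tables["sugar"], a_alloc[2], rng),
        sodium_mg=_amount_in_bin(tables.a_tables["sodium"], a_alloc[3], rng),
        fibre_g=_amount_in_bin(tables.fibre_aoac, c_alloc["fibre"], rng),
        protein_g=_amount_in_bin(tables.protein, c_alloc["protein"], rng),
        fvn_pct=_fvn_amount(c_alloc["fvn"], rng),
        fibre_basis="AOAC",
        serving_weight_g=100.0,
    )
    realized = compute_npm(profile, tables).total
    if realized != target_npm:
        raise NpiScoreError(
            f"internal error: inverted profile scores {realized}, wanted {target_npm}")
    return profile


@dataclass
class SyntheticStudy:
    """One generated corpus: video table, product records, nutrition tables."""

    config: GeneratorConfig
    videos: pd.DataFrame
    records: list[ProductRecord]
    tables: NutritionTables


def generate_study(config: GeneratorConfig | None = None) -> SyntheticStudy:
    """Draw one corpus under ``config`` (reproducible for a fixed seed).

    Foods drawn unscorable get no nutrition-table entry, so the scoring
    pipeline omits them with an explicit reason; scorable restaurant foods
    are emitted as pre-extracted report NPI values, other scorable foods as
    branded-label or generic-reference profiles.
    """
    config = config if config is not None else GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    n = config.n_videos
    featured = rng.random(n) < config.p_product
    videos = pd.DataFrame({
        "video_id": [f"v{i:06d}" for i in range(n)],
        "features_product": featured.astype(int),
    })

    type_labels = list(PRODUCT_TYPES)
    type_p = [config.type_probs[t] for t in type_labels]
    mixes = {"food": config.food_category_mix, "beverage": config.beverage_category_mix}
    npm_pmf = {stratum: dist.pmf() for stratum, dist in config.npm_dist.items()}

    records: list[ProductRecord] = []
    tables = NutritionTables()
    product_indices = np.flatnonzero(featured)
    for seq, video_index in enumerate(product_indices):
        ptype = type_labels[int(rng.choice(len(type_labels), p=type_p))]
        branded = bool(rng.random() < config.p_branded)
        stratum = "branded" if branded else "unbranded"
        if ptype == "supplement":
            category = "dietary supplement"
        else:
            mix = mixes[ptype][stratum]
            labels = list(mix)
            category = labels[int(rng.choice(len(labels), p=[mix[c] for c in labels]))]

        product_id = f"p{seq:06d}"
        name = f"{category} item {seq}"
        record = ProductRecord(
            product_id=product_id,
            video_id=f"v{int(video_index):06d}",
            name=name,
            product_type=ptype,
            branded=branded,
            restaurant=(ptype == "food" and category == RESTAURANT_CATEGORY),
        )
        records.append(record)

        if ptype != "food":
            continue
        if rng.random() < config.p_unscorable[stratum]:
            continue  # no table entry -> pipeline omits it
        npm_total = int(NPM_SUPPORT[int(rng.choice(
            len(NPM_SUPPORT), p=npm_pmf[stratum]))])
        if record.restaurant:
            tables.restaurant_report[name] = -2.0 * npm_total + 70.0
        else:
            profile = npm_to_profile(npm_total, rng=rng)
            if branded:
                tables.branded[product_id] = profile
            else:
                tables.generic[name.lower()] = profile

    return SyntheticStudy(config=config, videos=videos, records=records, tables=tables)
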