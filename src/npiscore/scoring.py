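"""NPM scoring, NPI conversion and healthfulness classification.

The 2004/05 UK Nutrient Profile Model (NPM) scores a food per 100 g:
A-points (0-10 each) penalise energy, saturated fat, total sugar and
sodium; C-points (0-5 each) credit fruit/vegetable/nut content, fibre and
protein. Protein credits are withheld when A >= 11 unless the food earns
the maximum 5 fruit/veg/nut points. The Nutrient Profile Index (NPI)
rescales the NPM total onto a nominal 1-100 scale via

    NPI = -2 * NPM + 70

so that the UK child-advertising cut-off NPM <= 3 maps exactly to
NPI >= 64, the healthy classification boundary. Every threshold comparison
is a strict inequality.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Mapping

from .errors import ConfigurationError, InputDomainError, UnscorableError
from .profiles import (
    KJ_PER_KCAL,
    HEALTHY_NPI_CUTOFF,
    NPIResult,
    NPMScore,
    NutrientProfile,
)
from .thresholds import (
    A_NUTRIENTS,
    ThresholdTables,
    default_fvn_lexicon,
    default_thresholds,
)

logger = logging.getLogger(__name__)

#: FVN percentage assigned by the first-five-ingredients assumption: the
#: stated lower bound "at least 50 %", worth exactly 1 C-point.
FVN_ASSUMED_PCT = 50.0
FVN_FIRST_N_INGREDIENTS = 5


def _scan(thresholds: tuple[float, ...], amount: float) -> int:
    # Points = number of (ascending) thresholds the amount strictly exceeds.
    points = 0
    for t in thresholds:
        if amount > t:
            points += 1
        else:
            break
    return points


def a_points(nutrient: str, amount: float,
             tables: ThresholdTables | None = None) -> int:
    """A-points (0-10) for one penalty nutrient.

    ``nutrient`` is one of ``energy`` (kJ), ``satfat`` (g), ``sugar`` (g)
    or ``sodium`` (mg); ``amount`` is per 100 g.
    """
    tables = tables or default_thresholds()
    if nutrient not in A_NUTRIENTS:
        raise ConfigurationError(f"unknown A-nutrient {nutrient!r}; expected one of {A_NUTRIENTS}")
    if amount < 0:
        raise InputDomainError(f"{nutrient} amount must be >= 0, got {amount}")
    return _scan(tables.a_tables[nutrient], amount)


def c_points(component: str, amount: float, fibre_basis: str = "AOAC",
             tables: ThresholdTables | None = None) -> int:
    """C-points (0-5) for one credit component.

    ``component`` is ``fvn`` (percent), ``fibre`` (g, on ``fibre_basis``)
    or ``protein`` (g); amounts are per 100 g.
    """
    tables = tables or default_thresholds()
    if amount < 0:
        raise InputDomainError(f"{component} amount must be >= 0, got {amount}")
    if component == "fvn":
        points = 0
        for threshold, pts in tables.fvn:
            if amount > threshold:
                points = pts
        return points
    if component == "fibre":
        return _scan(tables.fibre(fibre_basis), amount)
    if component == "protein":
        return _scan(tables.protein, amount)
    raise ConfigurationError(f"unknown C-component {component!r}")


def compute_npm(profile: NutrientProfile,
                tables: ThresholdTables | None = None) -> NPMScore:
    """Score one per-100 g profile under the NPM.

    All four A-nutrients must be present; a missing one raises
    :class:`UnscorableError` naming the absent fields (such foods are
    omitted from analysis). Missing C-components score 0 with a warning —
    credits can only lower the total, so 0 is the conservative value.
    """
    tables = tables or default_thresholds()
    missing = profile.missing_a_nutrients
    if missing:
        raise UnscorableError(
            f"cannot score: missing A-nutrient(s) {', '.join(missing)}", missing)

    a_e = a_points("energy", profile.energy_kj, tables)
    a_f = a_points("satfat", profile.satfat_g, tables)
    a_s = a_points("sugar", profile.sugar_g, tables)
    a_n = a_points("sodium", profile.sodium_mg, tables)
    a_sum = a_e + a_f + a_s + a_n

    c_values: dict[str, int] = {}
    for component, value in (("fvn", profile.fvn_pct),
                             ("fibre", profile.fibre_g),
                             ("protein", profile.protein_g)):
        if value is None:
            logger.warning("missing %s component scored as 0", component)
            c_values[component] = 0
        else:
            c_values[component] = c_points(component, value, profile.fibre_basis, tables)

    capped = a_sum >= 11 and c_values["fvn"] < 5
    total = a_sum - c_values["fvn"] - c_values["fibre"] - (0 if capped else c_values["protein"])
    return NPMScore(
        a_energy=a_e, a_satfat=a_f, a_sugar=a_s, a_sodium=a_n,
        c_fvn=c_values["fvn"], c_fibre=c_values["fibre"], c_protein=c_values["protein"],
        protein_capped=capped, total=total,
    )


def npm_to_npi(npm_total: float) -> NPIResult:
    """Convert an NPM total to the Nutrient Profile Index: -2*NPM + 70.

    The returned index is clamped to the nominal [1, 100] scale; the raw
    value drives the healthy classification (raw >= 64, i.e. NPM <= 3).
    """
    return NPIResult.from_raw(-2.0 * npm_total + 70.0)


def classify_healthfulness(result: NPIResult) -> str:
    """Label an NPI result ``healthy`` (raw NPI >= 64) or ``unhealthy``."""
    return "healthy" if result.npi_raw >= HEALTHY_NPI_CUTOFF else "unhealthy"


def normalize_to_100g(per_serving_amounts: Mapping[str, float],
                      serving_weight_g: float,
                      energy_unit: str = "kJ") -> NutrientProfile:
    """Rescale per-serving nutrition facts to the per-100 g basis NPM needs.

    ``per_serving_amounts`` maps any of ``energy``, ``satfat_g``,
    ``sugar_g``, ``sodium_mg``, ``fibre_g``, ``protein_g`` to per-serving
    amounts. Energy given in kcal is converted at 4.184 kJ/kcal before
    scaling. Missing keys stay ``None``.
    """
    if serving_weight_g is None:
        raise UnscorableError("serving weight required to normalize to 100 g",
                              ("serving_weight_g",))
    if serving_weight_g <= 0:
        raise InputDomainError(f"serving_weight_g must be > 0, got {serving_weight_g}")
    if energy_unit not in ("kJ", "kcal"):
        raise InputDomainError(f"energy_unit must be 'kJ' or 'kcal', got {energy_unit!r}")

    factor = 100.0 / serving_weight_g

    def scaled(key: str, convert: float = 1.0) -> float | None:
        value = per_serving_amounts.get(key)
        return None if value is None else float(value) * convert * factor

    energy_kj = scaled("energy", KJ_PER_KCAL if energy_unit == "kcal" else 1.0)
    return NutrientProfile(
        energy_kj=energy_kj,
        satfat_g=scaled("satfat_g"),
        sugar_g=scaled("sugar_g"),
        sodium_mg=scaled("sodium_mg"),
        fibre_g=scaled("fibre_g"),
        protein_g=scaled("protein_g"),
        fvn_pct=per_serving_amounts.get("fvn_pct"),  # a fraction, not scaled
        fibre_basis=str(per_serving_amounts.get("fibre_basis", "AOAC")),
        serving_weight_g=serving_weight_g,
        ingredients=per_serving_amounts.get("ingredients"),
    )


def apply_fvn_ingredient_rule(profile: NutrientProfile,
                              fvn_lexicon: frozenset[str] | set[str] | None = None,
                              ) -> NutrientProfile:
    """Fill an unknown fruit/veg/nut percentage from the ingredient list.

    If any of the first five ingredients matches the lexicon the food is
    assumed to contain at least 50 % fruit, vegetables or nuts, so
    ``fvn_pct`` is set to 50 (worth 1 C-point); otherwise 0. An explicit
    ``fvn_pct`` supplied by the caller is never overwritten.
    """
    if profile.fvn_pct is not None:
        return profile
    lexicon = fvn_lexicon if fvn_lexicon is not None else default_fvn_lexicon()
    if not profile.ingredients:
        logger.warning("no ingredient list and unknown fvn_pct; assuming 0 %%")
        return replace(profile, fvn_pct=0.0)
    first_five = profile.ingredients[:FVN_FIRST_N_INGREDIENTS]
    for ingredient in first_five:
        lowered = ingredient.strip().lower()
        if any(term in lowered for term in lexicon):
            return replace(profile, fvn_pct=FVN_ASSUMED_PCT)
    return replace(profile, fvn_pct=0.0)
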