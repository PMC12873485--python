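"""NPM component points, NPI conversion, normalization and the FVN rule."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from npiscore import (
    ConfigurationError,
    InputDomainError,
    NutrientProfile,
    UnscorableError,
    a_points,
    apply_fvn_ingredient_rule,
    c_points,
    classify_healthfulness,
    compute_npm,
    normalize_to_100g,
    npm_to_npi,
)

from conftest import oracle_npm_total, oracle_table_points, ORACLE_A


@pytest.mark.parametrize("nutrient, amount, expected", [
    ("energy", 0.0, 0),
    ("energy", 335.0, 0),     # strict inequality: equality earns no point
    ("energy", 335.1, 1),
    ("energy", 3350.1, 10),
    ("satfat", 1.0, 0),
    ("satfat", 1.01, 1),
    ("sugar", 20.0, 4),       # 20 > 18 and 20 <= 22.5
    ("sugar", 4.5, 0),
    ("sodium", 90.0, 0),
    ("sodium", 90.5, 1),
    ("sodium", 901.0, 10),
])
def test_a_points_strict_threshold_bins(nutrient, amount, expected):
    assert a_points(nutrient, amount) == expected
    assert a_points(nutrient, amount) == oracle_table_points(ORACLE_A[nutrient], amount)


@given(nutrient=st.sampled_from(["energy", "satfat", "sugar", "sodium"]),
       amount=st.floats(min_value=0, max_value=5000, allow_nan=False))
def test_a_points_matches_table_scan_oracle(nutrient, amount):
    assert a_points(nutrient, amount) == oracle_table_points(ORACLE_A[nutrient], amount)


@pytest.mark.parametrize("component, amount, kwargs, expected", [
    ("fvn", 0.0, {}, 0),
    ("fvn", 40.0, {}, 0),
    ("fvn", 50.0, {}, 1),
    ("fvn", 60.0, {}, 1),
    ("fvn", 61.0, {}, 2),
    ("fvn", 80.5, {}, 5),      # points jump 2 -> 5; 3 and 4 unattainable
    ("protein", 8.1, {}, 5),
    ("protein", 1.6, {}, 0),
    ("fibre", 0.8, {"fibre_basis": "NSP"}, 1),
    ("fibre", 0.8, {"fibre_basis": "AOAC"}, 0),
    ("fibre", 4.8, {"fibre_basis": "AOAC"}, 5),
])
def test_c_points_bins(component, amount, kwargs, expected):
    assert c_points(component, amount, **kwargs) == expected


def test_component_errors():
    with pytest.raises(InputDomainError):
        a_points("sugar", -1.0)
    with pytest.raises(ConfigurationError):
        a_points("transfat", 1.0)
    with pytest.raises(InputDomainError):
        c_points("protein", -0.1)
    with pytest.raises(ConfigurationError):
        c_points("calcium", 1.0)


def test_compute_npm_all_zero_profile():
    profile = NutrientProfile(energy_kj=0, satfat_g=0, sugar_g=0, sodium_mg=0,
                              fibre_g=0, protein_g=0, fvn_pct=0)
    score = compute_npm(profile)
    assert score.total == 0 and not score.protein_capped


def test_compute_npm_protein_cap_engages():
    # A = 5 + 4 + 4 + 3 = 16 >= 11 without 5 FVN points: protein credit withheld
    profile = NutrientProfile(energy_kj=2000, satfat_g=5, sugar_g=20, sodium_mg=300,
                              fvn_pct=0, fibre_g=2, protein_g=10, fibre_basis="NSP")
    score = compute_npm(profile)
    assert (score.a_energy, score.a_satfat, score.a_sugar, score.a_sodium) == (5, 4, 4, 3)
    assert score.protein_capped
    assert (score.c_fvn, score.c_fibre, score.c_protein) == (0, 2, 5)
    assert score.c_protein_applied == 0
    assert score.total == 14


def test_compute_npm_all_top_bins():
    profile = NutrientProfile(energy_kj=3400, satfat_g=11, sugar_g=46, sodium_mg=1000,
                              fvn_pct=0, fibre_g=0, protein_g=20)
    score = compute_npm(profile)
    assert score.a_total == 40 and score.protein_capped and score.total == 40


def test_compute_npm_missing_a_nutrient_unscorable():
    profile = NutrientProfile(energy_kj=500, satfat_g=None, sugar_g=3, sodium_mg=50)
    with pytest.raises(UnscorableError) as excinfo:
        compute_npm(profile)
    assert "satfat" in excinfo.value.missing


def test_compute_npm_missing_c_components_score_zero():
    profile = NutrientProfile(energy_kj=500, satfat_g=1, sugar_g=3, sodium_mg=50)
    assert compute_npm(profile).total == compute_npm(
        dataclasses.replace(profile, fibre_g=0.0, protein_g=0.0, fvn_pct=0.0)).total


@given(
    energy=st.floats(0, 4000), satfat=st.floats(0, 15), sugar=st.floats(0, 60),
    sodium=st.floats(0, 1200), fibre=st.floats(0, 8), protein=st.floats(0, 12),
    fvn=st.floats(0, 100), basis=st.sampled_from(["NSP", "AOAC"]),
)
def test_compute_npm_equals_brute_force_oracle(energy, satfat, sugar, sodium,
                                               fibre, protein, fvn, basis):
    profile = NutrientProfile(energy_kj=energy, satfat_g=satfat, sugar_g=sugar,
                              sodium_mg=sodium, fibre_g=fibre, protein_g=protein,
                              fvn_pct=fvn, fibre_basis=basis)
    assert compute_npm(profile).total == oracle_npm_total(profile)


@given(
    energy=st.floats(0, 4000), satfat=st.floats(0, 15), sugar=st.floats(0, 60),
    sodium=st.floats(0, 1200), bump=st.floats(0.1, 500),
    which=st.sampled_from(["energy_kj", "satfat_g", "sugar_g", "sodium_mg"]),
)
def test_increasing_a_nutrient_never_decreases_total(energy, satfat, sugar,
                                                     sodium, bump, which):
    base = NutrientProfile(energy_kj=energy, satfat_g=satfat, sugar_g=sugar,
                           sodium_mg=sodium, fibre_g=2, protein_g=4, fvn_pct=30)
    bumped = dataclasses.replace(base, **{which: getattr(base, which) + bump})
    assert compute_npm(bumped).total >= compute_npm(base).total


@given(
    energy=st.floats(0, 4000), sugar=st.floats(0, 60), fibre=st.floats(0, 6),
    fvn=st.floats(0, 90), bump=st.floats(0.1, 10),
    which=st.sampled_from(["fibre_g", "fvn_pct"]),
)
def test_increasing_credit_component_never_increases_total(energy, sugar, fibre,
                                                           fvn, bump, which):
    base = NutrientProfile(energy_kj=energy, satfat_g=3, sugar_g=sugar, sodium_mg=200,
                           fibre_g=fibre, protein_g=4, fvn_pct=fvn)
    new_value = getattr(base, which) + bump
    if which == "fvn_pct":
        new_value = min(new_value, 100.0)
    bumped = dataclasses.replace(base, **{which: new_value})
    assert compute_npm(bumped).total <= compute_npm(base).total


@given(
    energy=st.floats(0, 4000), satfat=st.floats(0, 15), sugar=st.floats(0, 60),
    sodium=st.floats(0, 1200), protein=st.floats(0, 12), fvn=st.floats(0, 100),
)
def test_protein_credit_applies_iff_not_capped(energy, satfat, sugar, sodium,
                                               protein, fvn):
    profile = NutrientProfile(energy_kj=energy, satfat_g=satfat, sugar_g=sugar,
                              sodium_mg=sodium, fibre_g=0, protein_g=protein,
                              fvn_pct=fvn)
    score = compute_npm(profile)
    if score.a_total < 11 or score.c_fvn == 5:
        assert not score.protein_capped
        assert score.c_protein_applied == score.c_protein
    else:
        assert score.protein_capped and score.c_protein_applied == 0


@pytest.mark.parametrize("npm_total, npi, npi_raw, healthy", [
    (3, 64.0, 64.0, True),     # the UK advertising cut-off maps to NPI 64
    (0, 70.0, 70.0, True),
    (4, 62.0, 62.0, False),
    (40, 1.0, -10.0, False),   # clamped to the nominal floor of 1
    (-15, 100.0, 100.0, True),
])
def test_npm_to_npi_formula_and_clamp(npm_total, npi, npi_raw, healthy):
    result = npm_to_npi(npm_total)
    assert result.npi == npi and result.npi_raw == npi_raw and result.healthy == healthy


def test_npi_conversion_is_bijective_and_cutoffs_coincide():
    for npm in range(-15, 41):
        result = npm_to_npi(npm)
        assert (70.0 - result.npi_raw) / 2.0 == npm
        assert result.healthy == (npm <= 3) == (result.npi_raw >= 64.0)


def test_classify_healthfulness_boundary():
    assert classify_healthfulness(npm_to_npi(3)) == "healthy"
    assert classify_healthfulness(npm_to_npi(3.05)) == "unhealthy"  # raw 63.9


def test_normalize_scales_by_serving_weight():
    profile = normalize_to_100g({"sugar_g": 10.0}, serving_weight_g=50.0)
    assert profile.sugar_g == pytest.approx(20.0)
    assert profile.energy_kj is None


def test_normalize_converts_kcal_to_kj():
    profile = normalize_to_100g({"energy": 100.0}, serving_weight_g=100.0,
                                energy_unit="kcal")
    assert profile.energy_kj == pytest.approx(418.4)


def test_normalize_identity_at_100g_serving():
    amounts = {"energy": 1200.0, "satfat_g": 3.0, "sugar_g": 12.0,
               "sodium_mg": 300.0, "fibre_g": 2.0, "protein_g": 5.0}
    profile = normalize_to_100g(amounts, serving_weight_g=100.0)
    assert (profile.energy_kj, profile.satfat_g, profile.sugar_g,
            profile.sodium_mg, profile.fibre_g, profile.protein_g) == (
        1200.0, 3.0, 12.0, 300.0, 2.0, 5.0)


def test_normalize_all_zero_stays_zero():
    profile = normalize_to_100g({"energy": 0.0, "sugar_g": 0.0}, serving_weight_g=30.0)
    assert profile.energy_kj == 0.0 and profile.sugar_g == 0.0


def test_normalize_rejects_bad_serving_weight():
    with pytest.raises(InputDomainError):
        normalize_to_100g({"sugar_g": 1.0}, serving_weight_g=0.0)
    with pytest.raises(UnscorableError):
        normalize_to_100g({"sugar_g": 1.0}, serving_weight_g=None)


def _profile_with_ingredients(ingredients, fvn=None):
    return NutrientProfile(energy_kj=500, satfat_g=1, sugar_g=30, sodium_mg=10,
                           fvn_pct=fvn, ingredients=tuple(ingredients))


def test_fvn_rule_fires_on_first_five_ingredients():
    profile = apply_fvn_ingredient_rule(
        _profile_with_ingredients(["strawberries", "sugar", "pectin"]))
    assert profile.fvn_pct == 50.0  # stated lower bound, worth 1 C-point


def test_fvn_rule_ignores_matches_beyond_fifth_ingredient():
    profile = apply_fvn_ingredient_rule(_profile_with_ingredients(
        ["wheat flour", "sugar", "palm fat", "cocoa", "salt", "hazelnuts"]))
    assert profile.fvn_pct == 0.0


def test_fvn_rule_no_match_sets_zero():
    profile = apply_fvn_ingredient_rule(_profile_with_ingredients(
        ["wheat flour", "sugar", "palm fat", "cocoa", "salt"]))
    assert profile.fvn_pct == 0.0


def test_fvn_rule_never_overwrites_explicit_value():
    profile = apply_fvn_ingredient_rule(
        _profile_with_ingredients(["strawberries"], fvn=85.0))
    assert profile.fvn_pct == 85.0


def test_fvn_rule_empty_ingredient_list_defaults_to_zero():
    profile = NutrientProfile(energy_kj=500, satfat_g=1, sugar_g=30, sodium_mg=10)
    assert apply_fvn_ingredient_rule(profile).fvn_pct == 0.0
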