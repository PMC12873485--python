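"""CSV input/output.

All files are UTF-8, comma-separated, header-required, "." decimal.

Products file: ``product_id, video_id, name, product_type, branded,
restaurant, top5, category`` (category optional; booleans as true/false).

Nutrition dialect (shared by the branded-label, generic-reference and
restaurant-menu tables): ``product_id, energy, energy_unit, satfat_g,
sugar_g, sodium_mg, salt_g, fibre_g, fibre_basis, protein_g, fvn_pct,
serving_weight_g, per_basis, ingredients`` where ``per_basis`` is
``100g`` or ``serving`` (per-serving rows are normalized on read),
``energy_unit`` is ``kJ`` or ``kcal``, ``salt_g`` substitutes for a
missing sodium value at 400 mg sodium per g salt, and ``ingredients`` is a
semicolon-joined ordered list. In the generic-reference table the
``product_id`` column holds the lookup *name* (lowercased on read); the
restaurant-menu table adds a leading ``restaurant`` column.

Restaurant report: ``name, npi`` with pre-extracted NPI values.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .catalog import NutritionTables, ProductRecord
from .errors import NpiScoreError, SchemaError
from .profiles import (
    SODIUM_MG_PER_G_SALT,
    KJ_PER_KCAL,
    NPIResult,
    NutrientProfile,
)
from .scoring import normalize_to_100g

PRODUCTS_COLUMNS = ("product_id", "video_id", "name", "product_type",
                    "branded", "restaurant", "top5", "category")
NUTRITION_COLUMNS = ("product_id", "energy", "energy_unit", "satfat_g",
                     "sugar_g", "sodium_mg", "salt_g", "fibre_g", "fibre_basis",
                     "protein_g", "fvn_pct", "serving_weight_g", "per_basis",
                     "ingredients")
SCORED_COLUMNS = ("product_id", "video_id", "name", "product_type", "branded",
                  "category", "nutrition_source", "a_energy", "a_satfat",
                  "a_sugar", "a_sodium", "c_fvn", "c_fibre", "c_protein",
                  "protein_capped", "npm_total", "npi", "npi_raw",
                  "classification", "omission_reason")


def _read_rows(path: str | Path, required: tuple[str, ...]) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header required")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
        return [dict(row) for row in reader]


def _parse_bool(value: str, column: str, row: int) -> bool:
    lowered = value.strip().lower()
    if lowered in ("true", "1", "yes"):
        return True
    if lowered in ("false", "0", "no", ""):
        return False
    raise SchemaError(f"{column} must be boolean-like, got {value!r}", row=row)


def _parse_float(value: str | None, column: str, row: int,
                 minimum: float | None = 0.0) -> float | None:
    if value is None or value.strip() == "":
        return None
    try:
        parsed = float(value)
    except ValueError:
        raise SchemaError(f"{column} must be numeric, got {value!r}", row=row) from None
    if minimum is not None and parsed < minimum:
        raise SchemaError(f"{column} must be >= {minimum}, got {parsed}", row=row)
    return parsed


def read_products_csv(path: str | Path) -> list[ProductRecord]:
    """Read and validate the products file (one product per video enforced
    downstream by the pipeline)."""
    required = ("product_id", "video_id", "name", "product_type", "branded")
    records = []
    for i, row in enumerate(_read_rows(path, required), start=2):
        if row["product_type"] not in ("food", "beverage", "supplement"):
            raise SchemaError(f"invalid product_type {row['product_type']!r}", row=i)
        records.append(ProductRecord(
            product_id=row["product_id"],
            video_id=row["video_id"],
            name=row["name"],
            product_type=row["product_type"],
            branded=_parse_bool(row.get("branded", ""), "branded", i),
            restaurant=_parse_bool(row.get("restaurant", ""), "restaurant", i),
            top5=_parse_bool(row.get("top5", ""), "top5", i),
            category=(row.get("category") or None),
        ))
    return records


def _profile_from_row(row: dict[str, str], i: int) -> NutrientProfile:
    energy = _parse_float(row.get("energy"), "energy", i)
    sodium = _parse_float(row.get("sodium_mg"), "sodium_mg", i)
    if sodium is None:
        salt = _parse_float(row.get("salt_g"), "salt_g", i)
        if salt is not None:
            sodium = salt * SODIUM_MG_PER_G_SALT
    energy_unit = (row.get("energy_unit") or "kJ").strip() or "kJ"
    if energy_unit not in ("kJ", "kcal"):
        raise SchemaError(f"energy_unit must be kJ or kcal, got {energy_unit!r}", row=i)
    fibre_basis = (row.get("fibre_basis") or "AOAC").strip() or "AOAC"
    per_basis = (row.get("per_basis") or "100g").strip() or "100g"
    ingredients_raw = (row.get("ingredients") or "").strip()
    ingredients = tuple(s.strip() for s in ingredients_raw.split(";") if s.strip()) or None
    amounts = {
        "energy": energy,
        "satfat_g": _parse_float(row.get("satfat_g"), "satfat_g", i),
        "sugar_g": _parse_float(row.get("sugar_g"), "sugar_g", i),
        "sodium_mg": sodium,
        "fibre_g": _parse_float(row.get("fibre_g"), "fibre_g", i),
        "protein_g": _parse_float(row.get("protein_g"), "protein_g", i),
        "fvn_pct": _parse_float(row.get("fvn_pct"), "fvn_pct", i),
        "fibre_basis": fibre_basis,
        "ingredients": ingredients,
    }
    serving = _parse_float(row.get("serving_weight_g"), "serving_weight_g", i, minimum=None)
    if per_basis == "serving":
        return normalize_to_100g(amounts, serving, energy_unit=energy_unit)
    if per_basis != "100g":
        raise SchemaError(f"per_basis must be '100g' or 'serving', got {per_basis!r}", row=i)
    if energy is not None and energy_unit == "kcal":
        amounts["energy"] = energy * KJ_PER_KCAL
    return NutrientProfile(
        energy_kj=amounts["energy"], satfat_g=amounts["satfat_g"],
        sugar_g=amounts["sugar_g"], sodium_mg=amounts["sodium_mg"],
        fibre_g=amounts["fibre_g"], protein_g=amounts["protein_g"],
        fvn_pct=amounts["fvn_pct"], fibre_basis=fibre_basis,
        serving_weight_g=serving, ingredients=ingredients,
    )


def read_nutrition_csv(path: str | Path, key_is_name: bool = False,
                       ) -> tuple[dict[str, NutrientProfile], dict[str, str]]:
    """Read one nutrition table; returns (profiles, problems).

    ``problems`` maps keys of rows that were present but unusable (for
    example a per-serving row without a serving weight) to the reason; the
    pipeline surfaces these as omission reasons.
    """
    profiles: dict[str, NutrientProfile] = {}
    problems: dict[str, str] = {}
    for i, row in enumerate(_read_rows(path, ("product_id",)), start=2):
        key = row["product_id"].lower() if key_is_name else row["product_id"]
        try:
            profiles[key] = _profile_from_row(row, i)
        except NpiScoreError as exc:
            if isinstance(exc, SchemaError):
                raise
            problems[key] = str(exc)
    return profiles, problems


def read_restaurant_report_csv(path: str | Path) -> dict[str, float]:
    report = {}
    for i, row in enumerate(_read_rows(path, ("name", "npi")), start=2):
        value = _parse_float(row["npi"], "npi", i, minimum=None)
        if value is None:
            raise SchemaError("npi value required", row=i)
        report[row["name"]] = value
    return report


def read_restaurant_menu_csv(path: str | Path) -> dict[str, list[NutrientProfile]]:
    menus: dict[str, list[NutrientProfile]] = {}
    for i, row in enumerate(_read_rows(path, ("restaurant", "product_id")), start=2):
        menus.setdefault(row["restaurant"], []).append(_profile_from_row(row, i))
    return menus


def load_tables(branded: str | Path | None = None,
                generic: str | Path | None = None,
                restaurant_report: str | Path | None = None,
                restaurant_menu: str | Path | None = None) -> NutritionTables:
    """Assemble the nutrition lookup tables from whichever files exist."""
    tables = NutritionTables()
    if branded is not None:
        tables.branded, problems = read_nutrition_csv(branded)
        tables.problems.update(problems)
    if generic is not None:
        tables.generic, problems = read_nutrition_csv(generic, key_is_name=True)
        tables.problems.update(problems)
    if restaurant_report is not None:
        tables.restaurant_report = read_restaurant_report_csv(restaurant_report)
    if restaurant_menu is not None:
        tables.restaurant_menu = read_restaurant_menu_csv(restaurant_menu)
    return tables


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _write_csv(path: str | Path, header: tuple[str, ...],
               rows: list[tuple]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(header)
        for row in rows:
            writer.writerow([_fmt(v) for v in row])


def write_products_csv(records: list[ProductRecord], path: str | Path) -> None:
    _write_csv(path, PRODUCTS_COLUMNS, [
        (r.product_id, r.video_id, r.name, r.product_type, r.branded,
         r.restaurant, r.top5, r.category)
        for r in records
    ])


def write_nutrition_csv(profiles: dict[str, NutrientProfile], path: str | Path) -> None:
    rows = []
    for key, p in profiles.items():
        rows.append((key, p.energy_kj, "kJ", p.satfat_g, p.sugar_g, p.sodium_mg,
                     None, p.fibre_g, p.fibre_basis, p.protein_g, p.fvn_pct,
                     p.serving_weight_g, "100g",
                     ";".join(p.ingredients) if p.ingredients else None))
    _write_csv(path, NUTRITION_COLUMNS, rows)


def write_restaurant_report_csv(report: dict[str, float], path: str | Path) -> None:
    _write_csv(path, ("name", "npi"), list(report.items()))


def write_videos_csv(videos: pd.DataFrame, path: str | Path) -> None:
    videos.to_csv(path, index=False)


def write_scored_csv(records: list[ProductRecord], path: str | Path) -> None:
    """One output row per product: category, source, NPM components, NPI
    (2 decimal places) and classification, or the omission reason."""
    rows = []
    for r in records:
        npm = r.npm
        npi = r.npi
        rows.append((
            r.product_id, r.video_id, r.name, r.product_type, r.branded,
            r.category, r.nutrition_source,
            *( (npm.a_energy, npm.a_satfat, npm.a_sugar, npm.a_sodium,
                npm.c_fvn, npm.c_fibre, npm.c_protein, npm.protein_capped,
                npm.total) if npm is not None else (None,) * 9 ),
            round(npi.npi, 2) if npi is not None else None,
            round(npi.npi_raw, 2) if npi is not None else None,
            ("healthy" if npi.healthy else "unhealthy") if npi is not None else None,
            r.omission_reason,
        ))
    _write_csv(path, SCORED_COLUMNS, rows)


def read_scored_csv(path: str | Path) -> list[ProductRecord]:
    """Read a scored file back into records (NPI and classification only;
    profiles are not round-tripped)."""
    records = []
    for i, row in enumerate(_read_rows(path, ("product_id", "video_id",
                                              "product_type", "branded")), start=2):
        record = ProductRecord(
            product_id=row["product_id"], video_id=row["video_id"],
            name=row.get("name", ""), product_type=row["product_type"],
            branded=_parse_bool(row.get("branded", ""), "branded", i),
            category=(row.get("category") or None),
            nutrition_source=(row.get("nutrition_source") or None),
            omission_reason=(row.get("omission_reason") or None),
        )
        npi_raw = _parse_float(row.get("npi_raw"), "npi_raw", i, minimum=None)
        if npi_raw is not None:
            npi = _parse_float(row.get("npi"), "npi", i, minimum=None)
            record.npi = NPIResult(npi=npi if npi is not None else npi_raw,
                                   npi_raw=npi_raw, healthy=npi_raw >= 64.0)
        records.append(record)
    return records


def write_study(study, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic corpus as the CSV set the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "videos": out / "videos.csv",
        "products": out / "products.csv",
        "branded": out / "branded_nutrition.csv",
        "generic": out / "generic_nutrition.csv",
        "restaurant_report": out / "restaurant_report.csv",
    }
    write_videos_csv(study.videos, paths["videos"])
    write_products_csv(study.records, paths["products"])
    write_nutrition_csv(study.tables.branded, paths["branded"])
    write_nutrition_csv(study.tables.generic, paths["generic"])
    write_restaurant_report_csv(study.tables.restaurant_report, paths["restaurant_report"])
    return paths
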