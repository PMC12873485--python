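"""Threshold tables for the UK 2004/05 Nutrient Profile Model.

The model awards "A" (penalty) points for energy, saturated fat, total
sugar and sodium, and "C" (credit) points for fruit/vegetable/nut content,
fibre and protein, each read off a fixed per-100 g threshold table with
strict-inequality bins. The tables ship as a human-editable YAML resource
(``data/npm2005.yaml``); alternative tables (for sensitivity analyses) can
be loaded from any file with the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError

A_NUTRIENTS = ("energy", "satfat", "sugar", "sodium")
C_COMPONENTS = ("fvn", "fibre", "protein")

_A_KEYS = {
    "energy": "energy_kj",
    "satfat": "satfat_g",
    "sugar": "sugar_g",
    "sodium": "sodium_mg",
}


@dataclass(frozen=True)
class ThresholdTables:
    """One versioned set of NPM component thresholds.

    Every list is strictly ascending; a component earns ``n`` points when
    its amount strictly exceeds the ``n``-th entry. ``fvn`` is a list of
    ``(threshold_pct, points)`` pairs because fruit/veg/nut points jump
    0 -> 1 -> 2 -> 5.
    """

    version: str
    a_tables: dict[str, tuple[float, ...]]
    fvn: tuple[tuple[float, int], ...]
    fibre_nsp: tuple[float, ...]
    fibre_aoac: tuple[float, ...]
    protein: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        for name, table in {**self.a_tables,
                            "fibre_nsp": self.fibre_nsp,
                            "fibre_aoac": self.fibre_aoac,
                            "protein": self.protein}.items():
            if not table or list(table) != sorted(table) or len(set(table)) != len(table):
                raise ConfigurationError(f"threshold table {name!r} must be strictly ascending")
        expected_a = {len(t) for t in self.a_tables.values()}
        if expected_a != {10}:
            raise ConfigurationError("each A-component table must have 10 thresholds")
        for t in (self.fibre_nsp, self.fibre_aoac, self.protein):
            if len(t) != 5:
                raise ConfigurationError("each C-component table must have 5 thresholds")
        if [p for _, p in self.fvn] != [1, 2, 5]:
            raise ConfigurationError("fvn points must be the sequence 1, 2, 5")

    def fibre(self, basis: str) -> tuple[float, ...]:
        if basis == "NSP":
            return self.fibre_nsp
        if basis == "AOAC":
            return self.fibre_aoac
        raise ConfigurationError(f"unknown fibre basis {basis!r} (expected 'NSP' or 'AOAC')")


def load_thresholds(path: str | Path | None = None) -> ThresholdTables:
    """Load threshold tables from ``path``, or the packaged 2004/05 defaults."""
    if path is None:
        text = resources.files("npiscore.data").joinpath("npm2005.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    try:
        a = raw["a_points"]
        c = raw["c_points"]
        return ThresholdTables(
            version=str(raw.get("version", "custom")),
            a_tables={k: tuple(float(x) for x in a[_A_KEYS[k]]) for k in A_NUTRIENTS},
            fvn=tuple((float(t), int(p)) for t, p in c["fvn_pct"]),
            fibre_nsp=tuple(float(x) for x in c["fibre_nsp_g"]),
            fibre_aoac=tuple(float(x) for x in c["fibre_aoac_g"]),
            protein=tuple(float(x) for x in c["protein_g"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed threshold table file: {exc}") from exc


@lru_cache(maxsize=1)
def default_thresholds() -> ThresholdTables:
    return load_thresholds()


@lru_cache(maxsize=1)
def default_fvn_lexicon() -> frozenset[str]:
    """Fruit/vegetable/nut ingredient terms for the first-five-ingredients rule."""
    text = resources.files("npiscore.data").joinpath("fvn_lexicon.yaml").read_text()
    terms = yaml.safe_load(text)["terms"]
    return frozenset(str(t).strip().lower() for t in terms)


def load_fvn_lexicon(path: str | Path) -> frozenset[str]:
    terms = yaml.safe_load(Path(path).read_text())["terms"]
    return frozenset(str(t).strip().lower() for t in terms)
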