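"""Descriptive summary layer: counts, percentages and stratified NPI stats.

Produces the study-style summary table: how many videos featured a
product, the food/beverage/supplement split, the branded share, category
frequency tables (overall and by brand status), and NPI mean/SD and
percent-unhealthy stratified by brand status. Percentages are rounded
half-up to 1 decimal place, means and SDs to 2; SDs use the sample (n-1)
denominator. Percentages are always recomputed from the module's own
numerators and denominators.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .catalog import ProductRecord
from .profiles import HEALTHY_NPI_CUTOFF

STRATA = ("overall", "branded", "unbranded")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 15.3308… % of 8871 prints as 15.3)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    if denominator == 0:
        raise ZeroDivisionError("percent with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass(frozen=True)
class StratumStats:
    n: int
    mean: float
    sd: float | None  # None when n < 2


@dataclass
class StudySummary:
    """All descriptive outputs of one study corpus (rounded, print-ready)."""

    n_videos: int
    n_product_videos: int
    pct_product_videos: float
    type_counts: dict[str, tuple[int, float]]
    branded_share_pct: float
    n_foods: int
    n_scored: int
    n_omitted: int
    pct_scored: float | None
    pct_omitted: float | None
    food_category_table: pd.DataFrame
    beverage_category_table: pd.DataFrame
    npi_stats: dict[str, StratumStats | None]
    unhealthy_pct: dict[str, float | None]
    consistency: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def stats_dict(s: StratumStats | None):
            return None if s is None else {"n": s.n, "mean": s.mean, "sd": s.sd}

        return {
            "n_videos": self.n_videos,
            "n_product_videos": self.n_product_videos,
            "pct_product_videos": self.pct_product_videos,
            "type_counts": {k: {"n": n, "pct": p} for k, (n, p) in self.type_counts.items()},
            "branded_share_pct": self.branded_share_pct,
            "foods": {"n": self.n_foods, "scored": self.n_scored,
                      "omitted": self.n_omitted, "pct_scored": self.pct_scored,
                      "pct_omitted": self.pct_omitted},
            "food_category_table": self.food_category_table.to_dict(orient="records"),
            "beverage_category_table": self.beverage_category_table.to_dict(orient="records"),
            "npi_stats": {k: stats_dict(v) for k, v in self.npi_stats.items()},
            "unhealthy_pct": self.unhealthy_pct,
            "consistency": self.consistency,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        lines = [
            "Study summary",
            "=============",
            f"Videos: {self.n_videos}; featuring a product: "
            f"{self.n_product_videos} ({self.pct_product_videos} %)",
        ]
        for ptype, (n, p) in self.type_counts.items():
            lines.append(f"  {ptype}: {n} ({p} %)")
        lines.append(f"Branded products: {self.branded_share_pct} %")
        lines.append(f"Foods scored: {self.n_scored} of {self.n_foods} "
                     f"({self.pct_scored} %); omitted: {self.n_omitted} "
                     f"({self.pct_omitted} %)")
        lines.append("")
        lines.append(f"Food categories (n = {self.n_foods})")
        lines.append(self.food_category_table.to_string(index=False))
        lines.append("")
        n_bev = self.type_counts.get("beverage", (0, 0.0))[0]
        lines.append(f"Beverage categories (n = {n_bev})")
        lines.append(self.beverage_category_table.to_string(index=False))
        lines.append("")
        lines.append("NPI of scored foods (mean, sd; % unhealthy)")
        for stratum in STRATA:
            stats = self.npi_stats.get(stratum)
            if stats is None:
                lines.append(f"  {stratum}: unavailable")
            else:
                sd = "n/a" if stats.sd is None else f"{stats.sd}"
                lines.append(f"  {stratum}: n={stats.n} mean={stats.mean} sd={sd} "
                             f"unhealthy={self.unhealthy_pct.get(stratum)} %")
        return "\n".join(lines) + "\n"


def _npi_values(records: list[ProductRecord]) -> list[float]:
    return [r.npi.npi for r in records if r.npi is not None]


def stratified_npi(records: list[ProductRecord]) -> dict[str, StratumStats | None]:
    """Mean/SD of NPI for scored foods, overall and by brand status.

    SD is the sample (n-1) standard deviation, unavailable below n = 2;
    empty strata are reported as ``None``.
    """
    scored = [r for r in records if r.product_type == "food" and r.npi is not None]
    out: dict[str, StratumStats | None] = {}
    for stratum in STRATA:
        subset = [r for r in scored
                  if stratum == "overall"
                  or (stratum == "branded") == r.branded]
        values = _npi_values(subset)
        if not values:
            out[stratum] = None
            continue
        n = len(values)
        mean = sum(values) / n
        sd = None
        if n >= 2:
            sd = round_half_up(math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)), 2)
        out[stratum] = StratumStats(n=n, mean=round_half_up(mean, 2), sd=sd)
    return out


def category_frequency_table(records: list[ProductRecord], product_type: str,
                             stratify_by_brand: bool = True) -> pd.DataFrame:
    """Counts and percents per category, sorted by descending count.

    Ties break alphabetically. Percent denominators are the stratum's own
    record count. With ``stratify_by_brand`` the table adds branded and
    unbranded count/percent columns (row counts are additive across the
    two strata).
    """
    subset = [r for r in records if r.product_type == product_type]
    if not subset:
        cols = ["category", "n", "pct"]
        if stratify_by_brand:
            cols += ["n_branded", "pct_branded", "n_unbranded", "pct_unbranded"]
        return pd.DataFrame(columns=cols)

    counts: dict[str, dict[str, int]] = {}
    for r in subset:
        row = counts.setdefault(r.category or "(uncategorized)",
                                {"n": 0, "n_branded": 0, "n_unbranded": 0})
        row["n"] += 1
        row["n_branded" if r.branded else "n_unbranded"] += 1

    total = len(subset)
    total_b = sum(1 for r in subset if r.branded)
    total_u = total - total_b
    rows = []
    for category in sorted(counts, key=lambda c: (-counts[c]["n"], c)):
        c = counts[category]
        row: dict[str, object] = {"category": category, "n": c["n"],
                                  "pct": percent(c["n"], total)}
        if stratify_by_brand:
            row["n_branded"] = c["n_branded"]
            row["pct_branded"] = percent(c["n_branded"], total_b) if total_b else None
            row["n_unbranded"] = c["n_unbranded"]
            row["pct_unbranded"] = percent(c["n_unbranded"], total_u) if total_u else None
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(records: list[ProductRecord], n_videos: int) -> StudySummary:
    """Build the full descriptive summary for one corpus.

    ``n_videos`` is the total number of videos screened (products appear in
    a subset of them). Raises if ``n_videos`` is smaller than the number of
    distinct product videos. Unhealthy percentages are computed over
    scored foods only; the NPI block is unavailable (not zero) when no
    food was scored.
    """
    distinct_videos = len({r.video_id for r in records})
    if n_videos < distinct_videos:
        raise ValueError(f"n_videos={n_videos} < {distinct_videos} distinct product videos")

    n_products = len(records)
    type_counts = {
        ptype: (sum(1 for r in records if r.product_type == ptype),)
        for ptype in ("food", "beverage", "supplement")
    }
    type_counts = {
        ptype: (n[0], percent(n[0], n_products) if n_products else 0.0)
        for ptype, n in type_counts.items()
    }
    n_branded = sum(1 for r in records if r.branded)

    foods = [r for r in records if r.product_type == "food"]
    scored = [r for r in foods if r.npi is not None]
    omitted = [r for r in foods if r.npi is None]

    npi_stats = stratified_npi(records)
    unhealthy: dict[str, float | None] = {}
    for stratum in STRATA:
        subset = [r for r in scored
                  if stratum == "overall" or (stratum == "branded") == r.branded]
        if not subset:
            unhealthy[stratum] = None
        else:
            n_unhealthy = sum(1 for r in subset if r.npi.npi_raw < HEALTHY_NPI_CUTOFF)
            unhealthy[stratum] = percent(n_unhealthy, len(subset))

    consistency: dict[str, float] = {}
    if npi_stats["overall"] is not None:
        parts = [npi_stats[s] for s in ("branded", "unbranded") if npi_stats[s] is not None]
        if parts:
            weighted = sum(s.n * s.mean for s in parts) / sum(s.n for s in parts)
            consistency["pooled_minus_weighted_mean"] = round_half_up(
                npi_stats["overall"].mean - weighted, 2)

    return StudySummary(
        n_videos=n_videos,
        n_product_videos=n_products,
        pct_product_videos=percent(n_products, n_videos) if n_videos else 0.0,
        type_counts=type_counts,
        branded_share_pct=percent(n_branded, n_products) if n_products else 0.0,
        n_foods=len(foods),
        n_scored=len(scored),
        n_omitted=len(omitted),
        pct_scored=percent(len(scored), len(foods)) if foods else None,
        pct_omitted=percent(len(omitted), len(foods)) if foods else None,
        food_category_table=category_frequency_table(records, "food"),
        beverage_category_table=category_frequency_table(records, "beverage"),
        npi_stats=npi_stats,
        unhealthy_pct=unhealthy,
        consistency=consistency,
    )
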