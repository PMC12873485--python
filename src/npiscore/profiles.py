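"""Domain types for nutrient profiling.

A :class:`NutrientProfile` holds the per-100 g amounts the 2004/05 UK
Nutrient Profile Model reads: the four "A" (penalty) nutrients — energy (kJ),
saturated fat (g), total sugar (g) and sodium (mg) — and the three "C"
(credit) components — fruit/vegetable/nut percentage, fibre (g, on either the
NSP or AOAC laboratory basis) and protein (g). A-nutrients may be ``None``
(missing), which makes the food unscorable; missing C-components are scored
as zero because credits can only improve the score.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputDomainError

KJ_PER_KCAL = 4.184
SODIUM_MG_PER_G_SALT = 400.0

FIBRE_BASES = ("NSP", "AOAC")


@dataclass(frozen=True)
class NutrientProfile:
    """Per-100 g nutrient amounts of one food, as consumed."""

    energy_kj: float | None
    satfat_g: float | None
    sugar_g: float | None
    sodium_mg: float | None
    fibre_g: float | None = None
    protein_g: float | None = None
    fvn_pct: float | None = None
    fibre_basis: str = "AOAC"
    serving_weight_g: float | None = None
    ingredients: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("energy_kj", "satfat_g", "sugar_g", "sodium_mg",
                     "fibre_g", "protein_g"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise InputDomainError(f"{name} must be >= 0, got {value}")
        if self.fvn_pct is not None and not 0 <= self.fvn_pct <= 100:
            raise InputDomainError(f"fvn_pct must be in [0, 100], got {self.fvn_pct}")
        if self.fibre_basis not in FIBRE_BASES:
            raise InputDomainError(f"fibre_basis must be one of {FIBRE_BASES}")
        if self.serving_weight_g is not None and self.serving_weight_g <= 0:
            raise InputDomainError("serving_weight_g must be positive when present")
        if self.ingredients is not None:
            object.__setattr__(self, "ingredients", tuple(self.ingredients))

    @property
    def missing_a_nutrients(self) -> tuple[str, ...]:
        return tuple(
            key for key, attr in (
                ("energy", "energy_kj"), ("satfat", "satfat_g"),
                ("sugar", "sugar_g"), ("sodium", "sodium_mg"),
            ) if getattr(self, attr) is None
        )


@dataclass(frozen=True)
class NPMScore:
    """Per-component NPM point allocation.

    ``total = A - c_fvn - c_fibre - c_protein_applied`` where the protein
    credit is withheld (``protein_capped``) whenever A-points reach 11 or
    more without maximum (5) fruit/veg/nut points.
    """

    a_energy: int
    a_satfat: int
    a_sugar: int
    a_sodium: int
    c_fvn: int
    c_fibre: int
    c_protein: int
    protein_capped: bool
    total: int

    @property
    def a_total(self) -> int:
        return self.a_energy + self.a_satfat + self.a_sugar + self.a_sodium

    @property
    def c_protein_applied(self) -> int:
        return 0 if self.protein_capped else self.c_protein


#: NPI score at and above which a food is classified healthy; the image of
#: the UK child-advertising NPM cut-off (NPM <= 3) under npi = -2*NPM + 70.
HEALTHY_NPI_CUTOFF = 64.0

NPI_MIN, NPI_MAX = 1.0, 100.0


@dataclass(frozen=True)
class NPIResult:
    """Nutrient Profile Index value and healthy/unhealthy classification.

    ``npi`` is clamped to the nominal [1, 100] scale; ``npi_raw`` keeps the
    unclamped value so that the healthy test (raw >= 64) and the NPM <= 3
    equivalence stay exact.
    """

    npi: float
    npi_raw: float
    healthy: bool

    @classmethod
    def from_raw(cls, npi_raw: float) -> "NPIResult":
        clamped = min(max(npi_raw, NPI_MIN), NPI_MAX)
        return cls(npi=clamped, npi_raw=npi_raw, healthy=npi_raw >= HEALTHY_NPI_CUTOFF)
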