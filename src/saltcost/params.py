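"""Declarative parameter model for salt-fortification cost scenarios.

A :class:`ParameterBook` is the complete description of one program
(iodized, dual, triple or quadruple fortified salt) under one salt-consumption
scenario: the fortification standard (mg nutrient per kg salt), the demand
parameters that turn population into metric tons of fortified salt, the
finance constants used for currency normalisation and capital annualisation,
the premix specification, and the list of costed activities.

Books are plain YAML documents; :func:`load_parameter_book` /
:func:`save_parameter_book` round-trip them with full validation.  All
monetary amounts inside a book are base-year USD (2021 in the shipped
Ethiopia books); historical amounts are normalised with the :mod:`finance`
operations before they enter a book.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "NUTRIENTS",
    "PROGRAM_NUTRIENTS",
    "PROGRAM_ORDER",
    "Phase",
    "Stakeholder",
    "Category",
    "FortificationStandard",
    "DemandParams",
    "FinanceParams",
    "CostRule",
    "ActivitySchedule",
    "FortificantCatalogEntry",
    "PremixSpec",
    "ParameterBook",
    "ParameterBookError",
    "load_parameter_book",
    "save_parameter_book",
    "validate_program_nesting",
]

#: Nutrients the model knows about, in program-nesting order.
NUTRIENTS = ("iodine", "folic_acid", "vitamin_b12", "zinc")

PROGRAM_ORDER = ("iodized", "dual", "triple", "quad")

#: Which nutrients each program fortifies with (monotone nesting).
PROGRAM_NUTRIENTS = {
    "iodized": frozenset({"iodine"}),
    "dual": frozenset({"iodine", "folic_acid"}),
    "triple": frozenset({"iodine", "folic_acid", "vitamin_b12"}),
    "quad": frozenset({"iodine", "folic_acid", "vitamin_b12", "zinc"}),
}


class Phase(str, enum.Enum):
    startup = "startup"
    recurring = "recurring"


class Stakeholder(str, enum.Enum):
    industry = "industry"
    government = "government"
    partner = "partner"


class Category(str, enum.Enum):
    """Closed activity taxonomy; reporting groups reconstruct table layouts from it."""

    premix = "premix"
    refinery_fortification = "refinery_fortification"
    refinery_qaqc = "refinery_qaqc"
    refinery_training = "refinery_training"
    refinery_admin = "refinery_admin"
    gov_refinery_monitoring = "gov_refinery_monitoring"
    gov_import_monitoring = "gov_import_monitoring"
    gov_market_monitoring = "gov_market_monitoring"
    gov_household_monitoring = "gov_household_monitoring"
    social_marketing = "social_marketing"
    gov_capacity_building = "gov_capacity_building"
    gov_admin = "gov_admin"
    planning = "planning"
    relabeling = "relabeling"


#: Category → stakeholder-facing cost group used in reports.
REFINERY_CATEGORIES = frozenset(
    {
        Category.refinery_fortification,
        Category.refinery_qaqc,
        Category.refinery_training,
        Category.refinery_admin,
        Category.relabeling,
    }
)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class FortificationStandard(_Model):
    """Target nutrient concentrations (mg nutrient / kg salt) for one program."""

    program_id: str
    concentrations: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "FortificationStandard":
        if self.program_id not in PROGRAM_ORDER:
            raise ValueError(f"unknown program_id {self.program_id!r}")
        unknown = set(self.concentrations) - set(NUTRIENTS)
        if unknown:
            raise ValueError(f"unknown nutrient(s): {sorted(unknown)}")
        for nut, conc in self.concentrations.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {nut}")
        if self.concentrations.get("iodine", 0.0) <= 0:
            raise ValueError("iodine concentration must be > 0 for every program")
        return self

    @property
    def nonzero_nutrients(self) -> frozenset[str]:
        return frozenset(n for n, c in self.concentrations.items() if c > 0)


class DemandParams(_Model):
    """Inputs that determine annual fortified-salt tonnage.

    ``per_capita_salt_g_per_day`` is discretionary plus manufactured-food salt
    (the fortifiable share is already folded in); ``compliance_fraction`` is
    the share of that salt actually fortified to standard.
    """

    population_by_year: dict[int, float]
    per_capita_salt_g_per_day: float = Field(gt=0)
    compliance_fraction: float = Field(ge=0.0, le=1.0)
    days_per_year: float = Field(default=365.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "DemandParams":
        for year, pop in self.population_by_year.items():
            if pop <= 0:
                raise ValueError(f"population must be > 0 (year {year})")
        return self


class FinanceParams(_Model):
    """Discounting, capital life, and currency-normalisation indices."""

    discount_rate: float = Field(ge=0.0)
    equipment_life_years: float = Field(ge=1.0)
    base_currency_year: int = 2021
    usd_deflator_by_year: dict[int, float] = Field(default_factory=dict)
    etb_cpi_by_year: dict[int, float] = Field(default_factory=dict)
    etb_per_usd_base_year: float = Field(default=43.7, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "FinanceParams":
        for name, table in (
            ("usd_deflator_by_year", self.usd_deflator_by_year),
            ("etb_cpi_by_year", self.etb_cpi_by_year),
        ):
            for year, idx in table.items():
                if idx <= 0:
                    raise ValueError(f"{name}[{year}] must be > 0")
        return self


class CostRule(_Model):
    """Exactly one way of costing an activity.

    * ``fixed_annual`` — base-year USD applied in each active year;
    * ``capital`` — lump sum annualised (equivalent annual cost) over the horizon;
    * ``per_mt`` — USD per metric ton of fortified salt in each active year;
    * ``premix_from_spec`` — the yearly cost is computed from the book's
      premix specification and demand (the premix line of the model).
    """

    fixed_annual: Optional[float] = Field(default=None, ge=0)
    capital: Optional[float] = Field(default=None, ge=0)
    per_mt: Optional[float] = Field(default=None, ge=0)
    premix_from_spec: bool = False

    @model_validator(mode="after")
    def _exactly_one(self) -> "CostRule":
        set_rules = [
            self.fixed_annual is not None,
            self.capital is not None,
            self.per_mt is not None,
            self.premix_from_spec,
        ]
        if sum(set_rules) != 1:
            raise ValueError("exactly one cost rule must be populated")
        return self

    @property
    def kind(self) -> str:
        if self.fixed_annual is not None:
            return "fixed_annual"
        if self.capital is not None:
            return "capital"
        if self.per_mt is not None:
            return "per_mt"
        return "premix_from_spec"


class ActivitySchedule(_Model):
    """One costed activity: who does it, when, and how its cost accrues."""

    activity_id: str
    label: str
    phase: Phase
    stakeholder: Stakeholder
    category: Category
    cost_rule: CostRule
    active_years: list[int]

    @model_validator(mode="after")
    def _check(self) -> "ActivitySchedule":
        if not self.active_years:
            raise ValueError(f"activity {self.activity_id}: empty active_years")
        self.__dict__["active_years"] = sorted(set(self.active_years))
        if self.cost_rule.kind == "capital" and self.phase is not Phase.startup and (
            self.category is not Category.refinery_fortification
        ):
            raise ValueError(
                f"activity {self.activity_id}: capital rule only on startup or "
                "fortification-equipment activities"
            )
        return self


class FortificantCatalogEntry(_Model):
    """A fortificant compound: which nutrient it delivers and at what price.

    ``nutrient_mass_fraction`` is the mass share of the compound that is the
    nutrient itself (e.g. iodine is ~59.3% of potassium iodate by mass).
    """

    nutrient: str
    compound: str
    nutrient_mass_fraction: float = Field(gt=0.0, le=1.0)
    price_per_kg_compound: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "FortificantCatalogEntry":
        if self.nutrient not in NUTRIENTS:
            raise ValueError(f"unknown nutrient {self.nutrient!r}")
        return self


class PremixSpec(_Model):
    """How a program's nutrients are delivered and costed.

    Sprayed nutrients are dosed as fortificant solutions at the refinery
    (potassium iodate, optionally folic acid); extruded nutrients arrive as
    encapsulated salt-like grains blended into the iodized salt at
    ``extruded_inclusion_rate_kg_per_mt`` kilograms per metric ton, costed as a
    delivered price per kg.  ``shipping_handling_per_mt_salt`` covers shipping,
    storage and local transport per ton of salt.
    """

    sprayed_nutrients: list[str] = Field(default_factory=list)
    extruded_nutrients: list[str] = Field(default_factory=list)
    extruded_inclusion_rate_kg_per_mt: float = Field(default=0.0, ge=0)
    extruded_price_per_kg: float = Field(default=0.0, ge=0)
    shipping_handling_per_mt_salt: float = Field(default=0.0, ge=0)
    overage_fraction: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "PremixSpec":
        unknown = (set(self.sprayed_nutrients) | set(self.extruded_nutrients)) - set(
            NUTRIENTS
        )
        if unknown:
            raise ValueError(f"unknown nutrient(s): {sorted(unknown)}")
        overlap = set(self.sprayed_nutrients) & set(self.extruded_nutrients)
        if overlap:
            raise ValueError(f"nutrient(s) both sprayed and extruded: {sorted(overlap)}")
        if bool(self.extruded_nutrients) != (self.extruded_inclusion_rate_kg_per_mt > 0):
            raise ValueError(
                "extruded inclusion rate must be > 0 exactly when extruded "
                "nutrients are present"
            )
        return self

    @property
    def delivered_nutrients(self) -> frozenset[str]:
        return frozenset(self.sprayed_nutrients) | frozenset(self.extruded_nutrients)


class ParameterBook(_Model):
    """Complete declarative model for one program × scenario."""

    book_id: str
    scenario: str = ""
    program: FortificationStandard
    demand: DemandParams
    finance: FinanceParams
    activities: list[ActivitySchedule]
    horizon_start: int
    horizon_end: int
    phase_in_years: int = Field(default=0, ge=0)
    premix_spec: Optional[PremixSpec] = None
    baseline_premix_spec: Optional[PremixSpec] = None
    catalog: list[FortificantCatalogEntry] = Field(default_factory=list)
    baseline_book_id: Optional[str] = None
    notes: str = ""

    @model_validator(mode="after")
    def _check(self) -> "ParameterBook":
        if self.horizon_end < self.horizon_start:
            raise ValueError("horizon_end before horizon_start")
        n_years = self.horizon_end - self.horizon_start + 1
        if n_years < self.phase_in_years:
            raise ValueError("horizon shorter than phase_in_years")
        if self.program.program_id == "iodized" and self.phase_in_years != 0:
            raise ValueError("iodized program must have phase_in_years = 0")
        horizon = set(self.years)
        phase_in = set(self.phase_in_calendar_years)
        for act in self.activities:
            if not set(act.active_years) <= horizon:
                raise ValueError(
                    f"activity {act.activity_id}: active_years outside horizon "
                    f"{self.horizon_start}-{self.horizon_end}"
                )
            if act.phase is Phase.startup and not set(act.active_years) <= phase_in:
                raise ValueError(
                    f"activity {act.activity_id}: startup activities may only be "
                    "active in phase-in years"
                )
            if act.cost_rule.premix_from_spec and self.premix_spec is None:
                raise ValueError(
                    f"activity {act.activity_id}: premix_from_spec rule requires "
                    "a premix_spec on the book"
                )
        missing = {y for y in self.years if y not in self.demand.population_by_year}
        if missing:
            raise ValueError(f"population missing for horizon year(s) {sorted(missing)}")
        if self.premix_spec is not None:
            delivered = self.premix_spec.delivered_nutrients
            required = self.program.nonzero_nutrients
            if delivered != required:
                raise ValueError(
                    "premix spec must deliver exactly the program's nonzero "
                    f"nutrients; spec {sorted(delivered)} vs standard {sorted(required)}"
                )
        return self

    @property
    def years(self) -> list[int]:
        return list(range(self.horizon_start, self.horizon_end + 1))

    @property
    def phase_in_calendar_years(self) -> list[int]:
        return self.years[: self.phase_in_years]

    @property
    def n_years(self) -> int:
        return self.horizon_end - self.horizon_start + 1


class ParameterBookError(ValueError):
    """Raised when a parameter book fails schema or invariant validation."""


def _int_keys(d: dict) -> dict:
    return {int(k): v for k, v in d.items()}


def book_from_dict(payload: dict) -> ParameterBook:
    """Validate a plain mapping (e.g. parsed YAML) into a :class:`ParameterBook`."""
    if not isinstance(payload, dict):
        raise ParameterBookError("parameter book must be a mapping")
    payload = dict(payload)
    # YAML round-trips mapping keys as strings; coerce year-keyed tables.
    demand = payload.get("demand")
    if isinstance(demand, dict) and isinstance(demand.get("population_by_year"), dict):
        demand = dict(demand)
        demand["population_by_year"] = _int_keys(demand["population_by_year"])
        payload["demand"] = demand
    finance = payload.get("finance")
    if isinstance(finance, dict):
        finance = dict(finance)
        for key in ("usd_deflator_by_year", "etb_cpi_by_year"):
            if isinstance(finance.get(key), dict):
                finance[key] = _int_keys(finance[key])
        payload["finance"] = finance
    try:
        return ParameterBook.model_validate(payload)
    except ValidationError as exc:
        first = exc.errors()[0]
        path = ".".join(str(p) for p in first["loc"])
        raise ParameterBookError(f"{path}: {first['msg']}") from exc


def book_to_dict(book: ParameterBook) -> dict:
    """Serialise a book to a plain mapping suitable for YAML/JSON."""
    return book.model_dump(mode="json", exclude_none=True)


def load_parameter_book(path: str | Path) -> ParameterBook:
    """Load and fully validate one parameter book from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise ParameterBookError(f"no such parameter book: {path}")
    with open(path) as fh:
        try:
            payload = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ParameterBookError(f"{path}: not valid YAML ({exc})") from exc
    return book_from_dict(payload)


def save_parameter_book(book: ParameterBook, path: str | Path) -> None:
    """Write a book to YAML such that loading it back yields an equal book."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(book_to_dict(book), fh, sort_keys=False, default_flow_style=False)


def validate_program_nesting(books: list[ParameterBook]) -> list[str]:
    """Cross-check a family of program books for consistency.

    Confirms that nonzero nutrient sets nest monotonically
    (iodized ⊂ dual ⊂ triple ⊂ quad) and that demand and finance blocks are
    identical across the family.  Report-only: returns a list of discrepancy
    strings (empty when consistent).
    """
    discrepancies: list[str] = []
    by_program = {b.program.program_id: b for b in books}
    present = [p for p in PROGRAM_ORDER if p in by_program]
    if len(present) < 2:
        discrepancies.append("need books for at least two programs to check nesting")
        return discrepancies
    for program in present:
        book = by_program[program]
        expected = PROGRAM_NUTRIENTS[program]
        actual = book.program.nonzero_nutrients
        for nut in expected - actual:
            discrepancies.append(f"{program} lacks {nut}")
        for nut in actual - expected:
            discrepancies.append(f"{program} has unexpected nutrient {nut}")
    for prev, cur in zip(present, present[1:]):
        a = by_program[prev].program.nonzero_nutrients
        b = by_program[cur].program.nonzero_nutrients
        if not a <= b:
            discrepancies.append(f"{prev} nutrients not a subset of {cur}")
    ref = by_program[present[0]]
    for program in present[1:]:
        book = by_program[program]
        if book.demand != ref.demand:
            discrepancies.append(
                f"{program} demand block differs from {present[0]}"
            )
        if book.finance != ref.finance:
            discrepancies.append(
                f"{program} finance block differs from {present[0]}"
            )
    return discrepancies
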