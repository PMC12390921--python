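"""Premix costing for sprayed fortificants and extruded, encapsulated grains.

Two delivery routes exist at a salt refinery:

* **sprayed** — fortificant compounds (potassium iodate, optionally folic
  acid) dissolved and sprayed onto the salt; cost scales with the target
  concentration divided by the nutrient mass fraction of the compound;
* **extruded** — micronutrients extruded into encapsulated salt-like grains
  off site and blended into the iodized salt at a fixed inclusion rate, costed
  as a delivered price per kg of premix.

A shipping/handling adder per MT of salt is split across the two routes in
proportion to their fortificant cost.  Concentrations are nutrient mass
(mg/kg), not compound mass.
"""

from __future__ import annotations

from dataclasses import dataclass

from .demand import annual_fortified_salt_mt
from .params import (
    FortificantCatalogEntry,
    FortificationStandard,
    ParameterBook,
    PremixSpec,
)

__all__ = [
    "compound_mass_per_mt",
    "sprayed_premix_cost_per_mt",
    "extruded_premix_cost_per_mt",
    "premix_cost_per_mt",
    "annual_premix_cost",
    "PremixCostBreakdown",
]


def compound_mass_per_mt(
    concentration_mg_per_kg: float, nutrient_mass_fraction: float
) -> float:
    """Kilograms of fortificant compound per MT of salt.

    mg nutrient per kg salt ≡ g nutrient per MT salt, so dividing by 1000
    gives kg nutrient per MT, and dividing by the nutrient mass fraction gives
    kg of compound.
    """
    if nutrient_mass_fraction <= 0:
        raise ValueError("nutrient_mass_fraction must be > 0")
    if concentration_mg_per_kg < 0:
        raise ValueError("concentration must be >= 0")
    return concentration_mg_per_kg * 1e-3 / nutrient_mass_fraction


def _catalog_entry(
    catalog: list[FortificantCatalogEntry], nutrient: str
) -> FortificantCatalogEntry:
    for entry in catalog:
        if entry.nutrient == nutrient:
            return entry
    raise ValueError(f"no fortificant catalog entry for nutrient {nutrient!r}")


def _sprayed_fortificant_cost(
    standard: FortificationStandard,
    spec: PremixSpec,
    catalog: list[FortificantCatalogEntry],
) -> float:
    total = 0.0
    for nutrient in spec.sprayed_nutrients:
        conc = standard.concentrations.get(nutrient, 0.0)
        entry = _catalog_entry(catalog, nutrient)
        mass = compound_mass_per_mt(conc, entry.nutrient_mass_fraction)
        total += mass * entry.price_per_kg_compound * (1.0 + spec.overage_fraction)
    return total


def _extruded_base_cost(spec: PremixSpec) -> float:
    return spec.extruded_inclusion_rate_kg_per_mt * spec.extruded_price_per_kg


@dataclass(frozen=True)
class PremixCostBreakdown:
    """Per-MT premix cost split by route; ``total`` includes shipping."""

    sprayed: float
    extruded: float
    shipping: float

    @property
    def total(self) -> float:
        return self.sprayed + self.extruded + self.shipping


def premix_cost_per_mt(
    standard: FortificationStandard,
    spec: PremixSpec,
    catalog: list[FortificantCatalogEntry],
) -> PremixCostBreakdown:
    """Full premix cost per MT of fortified salt, by route."""
    return PremixCostBreakdown(
        sprayed=_sprayed_fortificant_cost(standard, spec, catalog),
        extruded=_extruded_base_cost(spec),
        shipping=spec.shipping_handling_per_mt_salt if spec.delivered_nutrients else 0.0,
    )


def sprayed_premix_cost_per_mt(
    standard: FortificationStandard,
    spec: PremixSpec,
    catalog: list[FortificantCatalogEntry],
) -> float:
    """Sprayed-route cost per MT, including its share of shipping/handling.

    Shipping is prorated by fortificant cost; with no sprayed nutrients the
    result is zero (including zero shipping).
    """
    sprayed = _sprayed_fortificant_cost(standard, spec, catalog)
    if sprayed == 0.0:
        return 0.0
    extruded = _extruded_base_cost(spec)
    share = sprayed / (sprayed + extruded) if sprayed + extruded > 0 else 0.0
    return sprayed + spec.shipping_handling_per_mt_salt * share


def extruded_premix_cost_per_mt(spec: PremixSpec) -> float:
    """Extruded-route cost per MT: inclusion rate × delivered price.

    When the spec has no sprayed nutrients the whole shipping adder belongs to
    this route; otherwise the split is handled by :func:`premix_cost_per_mt`.
    """
    base = _extruded_base_cost(spec)
    if base > 0 and not spec.sprayed_nutrients:
        return base + spec.shipping_handling_per_mt_salt
    return base


def _baseline_standard(book: ParameterBook) -> FortificationStandard:
    """Iodine-only standard in force during phase-in years."""
    return FortificationStandard(
        program_id="iodized",
        concentrations={"iodine": book.program.concentrations["iodine"]},
    )


def annual_premix_cost(book: ParameterBook, year: int) -> float:
    """Total premix cost (USD) for one horizon year.

    During the phase-in years of an expansion book the baseline iodization
    program continues, so the baseline (iodine-only) premix spec applies; the
    full program spec applies from the first full-program year onward.
    """
    if year not in book.demand.population_by_year and year not in book.years:
        raise ValueError(f"year {year} outside book horizon")
    if book.premix_spec is None:
        return 0.0
    mt = annual_fortified_salt_mt(book.demand, year)
    if mt == 0.0:
        return 0.0
    if year in book.phase_in_calendar_years and book.baseline_premix_spec is not None:
        spec = book.baseline_premix_spec
        standard = _baseline_standard(book)
    else:
        spec = book.premix_spec
        standard = book.program
    return premix_cost_per_mt(standard, spec, book.catalog).total * mt
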