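"""One-way and combined ±fraction sensitivity on uncertain cost components.

Three components of a fortification cost model are conventionally treated as
most uncertain and varied together or one at a time:

* ``premix_price`` — every premix monetary input (fortificant prices
  including potassium iodate, extruded premix price, shipping/handling) plus
  any premix-category activity amounts;
* ``refinery_fortification_cost`` — the refinery fortification line (labor,
  power/fuel, annualised equipment, maintenance) — not QA/QC, training or
  administration;
* ``government_monitoring_cost`` — government refinery, import and household
  monitoring (market monitoring is excluded by default; the mapping is
  overridable).

Each variation re-runs the full cost engine on a scaled copy of the book —
there is no closed-form shortcut — so the model's linearity (base − low ==
high − base) acts as an independent check on the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

from .engine import CostReport, compute_report
from .params import Category, ParameterBook

__all__ = [
    "SensitivitySpec",
    "SensitivityResult",
    "run_sensitivity",
    "scaled_book",
    "COMPONENT_CATEGORIES",
]

#: Default component → activity-category mapping.
COMPONENT_CATEGORIES: dict[str, frozenset[Category]] = {
    "premix_price": frozenset({Category.premix}),
    "refinery_fortification_cost": frozenset({Category.refinery_fortification}),
    "government_monitoring_cost": frozenset(
        {
            Category.gov_refinery_monitoring,
            Category.gov_import_monitoring,
            Category.gov_household_monitoring,
        }
    ),
}

ALL_COMPONENTS = tuple(COMPONENT_CATEGORIES)


@dataclass(frozen=True)
class SensitivitySpec:
    varied_components: tuple[str, ...] = ALL_COMPONENTS
    fraction: float = 0.30
    mode: Literal["one_way", "best_case", "worst_case"] = "one_way"

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        if not self.varied_components:
            raise ValueError("varied_components must be non-empty")
        unknown = set(self.varied_components) - set(COMPONENT_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown sensitivity component(s): {sorted(unknown)}")


@dataclass
class SensitivityResult:
    """Per-MT annual-average cost under base, low and high variation."""

    book_id: str
    fraction: float
    base_per_mt: float
    one_way: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    best_case_per_mt: Optional[float] = None
    worst_case_per_mt: Optional[float] = None

    def rows(self) -> list[dict]:
        """CSV-ready rows suitable for tornado plotting."""
        out = [
            {
                "component": comp,
                "low_per_mt": low,
                "base_per_mt": base,
                "high_per_mt": high,
            }
            for comp, (low, base, high) in self.one_way.items()
        ]
        if self.best_case_per_mt is not None:
            out.append(
                {
                    "component": "best_case",
                    "low_per_mt": self.best_case_per_mt,
                    "base_per_mt": self.base_per_mt,
                    "high_per_mt": self.base_per_mt,
                }
            )
        if self.worst_case_per_mt is not None:
            out.append(
                {
                    "component": "worst_case",
                    "low_per_mt": self.base_per_mt,
                    "base_per_mt": self.base_per_mt,
                    "high_per_mt": self.worst_case_per_mt,
                }
            )
        return out


def _scale_premix(book: ParameterBook, factor: float) -> None:
    """Scale every premix monetary input in place (on a deep copy)."""
    for entry in book.catalog:
        entry.price_per_kg_compound = entry.price_per_kg_compound * factor
    for spec in (book.premix_spec, book.baseline_premix_spec):
        if spec is not None:
            spec.extruded_price_per_kg = spec.extruded_price_per_kg * factor
            spec.shipping_handling_per_mt_salt = (
                spec.shipping_handling_per_mt_salt * factor
            )


def scaled_book(
    book: ParameterBook,
    factors: Mapping[str, float],
    component_map: Mapping[str, frozenset[Category]] | None = None,
) -> ParameterBook:
    """Deep-copied book with each component's monetary inputs scaled.

    ``factors`` maps component name → multiplicative factor (e.g. 1.3 for
    +30%).  Activities outside the varied categories are untouched.
    """
    component_map = dict(component_map or COMPONENT_CATEGORIES)
    copy = book.model_copy(deep=True)
    for component, factor in factors.items():
        categories = component_map[component]
        if component == "premix_price":
            _scale_premix(copy, factor)
        for act in copy.activities:
            if act.category in categories and not act.cost_rule.premix_from_spec:
                rule = act.cost_rule
                if rule.fixed_annual is not None:
                    rule.fixed_annual = rule.fixed_annual * factor
                elif rule.capital is not None:
                    rule.capital = rule.capital * factor
                elif rule.per_mt is not None:
                    rule.per_mt = rule.per_mt * factor
    return copy


def run_sensitivity(
    book: ParameterBook,
    spec: SensitivitySpec,
    component_map: Mapping[str, frozenset[Category]] | None = None,
    per_mt_denominator: str = "fortified",
) -> SensitivityResult:
    """Recompute the full cost report under ±fraction variation.

    One-way results are produced for every varied component; combined
    best-case (all components down) and worst-case (all up) are always
    reported alongside.
    """

    def per_mt(b: ParameterBook) -> float:
        return compute_report(b, per_mt_denominator=per_mt_denominator).annual_average_per_mt

    base = per_mt(book)
    result = SensitivityResult(
        book_id=book.book_id, fraction=spec.fraction, base_per_mt=base
    )
    f = spec.fraction
    for component in spec.varied_components:
        low = per_mt(scaled_book(book, {component: 1.0 - f}, component_map))
        high = per_mt(scaled_book(book, {component: 1.0 + f}, component_map))
        if not (low <= base <= high):
            raise AssertionError(
                f"sensitivity ordering violated for {component}: "
                f"{low} / {base} / {high}"
            )
        result.one_way[component] = (low, base, high)
    all_down = {c: 1.0 - f for c in spec.varied_components}
    all_up = {c: 1.0 + f for c in spec.varied_components}
    result.best_case_per_mt = per_mt(scaled_book(book, all_down, component_map))
    result.worst_case_per_mt = per_mt(scaled_book(book, all_up, component_map))
    return result
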