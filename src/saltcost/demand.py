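"""Fortified-salt demand: population × per-capita intake × compliance.

Quantities are metric tons (MT) of salt per year.  ``fortifiable`` tonnage is
all discretionary plus manufactured-food salt; ``fortified`` tonnage applies
the compliance fraction (the share actually fortified to the national
standard), which is the denominator convention used in cost-per-MT reporting.
"""

from __future__ import annotations

import pandas as pd

from .params import DemandParams

__all__ = [
    "annual_fortifiable_salt_mt",
    "annual_fortified_salt_mt",
    "demand_series",
]

_G_PER_MT = 1e6


def annual_fortifiable_salt_mt(demand: DemandParams, year: int) -> float:
    """Total fortifiable salt (MT) consumed in *year*, before compliance."""
    try:
        population = demand.population_by_year[year]
    except KeyError:
        raise ValueError(f"no population estimate for year {year}") from None
    grams = population * demand.per_capita_salt_g_per_day * demand.days_per_year
    return grams / _G_PER_MT


def annual_fortified_salt_mt(demand: DemandParams, year: int) -> float:
    """Salt fortified to standard (MT) in *year*: fortifiable × compliance."""
    return annual_fortifiable_salt_mt(demand, year) * demand.compliance_fraction


def demand_series(demand: DemandParams, years: list[int]) -> pd.DataFrame:
    """Year-by-year demand table (exportable as CSV)."""
    rows = [
        {
            "year": y,
            "population": demand.population_by_year[y],
            "fortifiable_mt": annual_fortifiable_salt_mt(demand, y),
            "fortified_mt": annual_fortified_salt_mt(demand, y),
        }
        for y in years
    ]
    return pd.DataFrame(rows)
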