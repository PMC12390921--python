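"""Currency normalisation and capital annualisation.

All model arithmetic runs in base-year USD (2021 for the shipped Ethiopia
books).  Historical USD amounts are restated with a GDP implicit price
deflator; Ethiopian Birr amounts are first restated with the local CPI and
then converted at the base-year average exchange rate.  Equipment lump sums
are converted to an equivalent annual cost (EAC): the constant annual payment
whose present value at the discount rate over the asset's useful life equals
the capital outlay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .params import FinanceParams

__all__ = ["MoneyAmount", "to_base_usd", "equivalent_annual_cost", "annuity_factor"]


@dataclass(frozen=True)
class MoneyAmount:
    """An amount of money with its currency and the year it was stated in."""

    value: float
    currency: Literal["USD", "ETB"]
    year: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("cost inputs must be non-negative")
        if self.currency not in ("USD", "ETB"):
            raise ValueError(f"unknown currency {self.currency!r}")


def _index(table: dict[int, float], year: int, name: str) -> float:
    try:
        return table[year]
    except KeyError:
        raise ValueError(f"{name} has no entry for year {year}") from None


def to_base_usd(amount: MoneyAmount, finance: FinanceParams) -> float:
    """Restate *amount* in base-year USD.

    USD path: multiply by deflator(base)/deflator(year).  ETB path: multiply
    by CPI(base)/CPI(year), then divide by the base-year ETB/USD rate.
    Amounts already in base-year USD pass through unchanged.
    """
    base = finance.base_currency_year
    if amount.currency == "USD":
        if amount.year == base:
            return amount.value
        defl = finance.usd_deflator_by_year
        return amount.value * _index(defl, base, "usd_deflator_by_year") / _index(
            defl, amount.year, "usd_deflator_by_year"
        )
    cpi = finance.etb_cpi_by_year
    if amount.year == base:
        etb_base = amount.value
    else:
        etb_base = amount.value * _index(cpi, base, "etb_cpi_by_year") / _index(
            cpi, amount.year, "etb_cpi_by_year"
        )
    return etb_base / finance.etb_per_usd_base_year


def annuity_factor(rate: float, life_years: float) -> float:
    """Capital-recovery factor: EAC per unit of capital.

    ``rate / (1 - (1+rate)^-life)`` for positive rates, with the straight-line
    limit ``1/life`` at rate zero.
    """
    if life_years < 1:
        raise ValueError("life_years must be >= 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0:
        return 1.0 / life_years
    return rate / (1.0 - (1.0 + rate) ** (-life_years))


def equivalent_annual_cost(capital: float, rate: float, life_years: float) -> float:
    """Constant annual payment equivalent to a capital outlay.

    Discounting the returned payment over ``life_years`` at ``rate`` recovers
    ``capital`` exactly (net-present-value round trip).
    """
    if capital < 0:
        raise ValueError("capital must be >= 0")
    return capital * annuity_factor(rate, life_years)
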