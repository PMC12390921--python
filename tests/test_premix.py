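"""Premix costing: compound conversion, sprayed and extruded routes, phasing."""

import pytest

from saltcost import (
    annual_premix_cost,
    compound_mass_per_mt,
    extruded_premix_cost_per_mt,
    premix_cost_per_mt,
    sprayed_premix_cost_per_mt,
)
from saltcost.params import (
    FortificantCatalogEntry,
    FortificationStandard,
    PremixSpec,
)

IODINE_IN_KIO3 = 0.5931  # from molar masses I 126.90 / KIO3 214.00


def catalog(kio3_price=20.0, fa_price=90.0):
    return [
        FortificantCatalogEntry(
            nutrient="iodine",
            compound="potassium iodate",
            nutrient_mass_fraction=IODINE_IN_KIO3,
            price_per_kg_compound=kio3_price,
        ),
        FortificantCatalogEntry(
            nutrient="folic_acid",
            compound="folic acid",
            nutrient_mass_fraction=1.0,
            price_per_kg_compound=fa_price,
        ),
    ]


class TestCompoundMass:
    def test_unit_identity(self):
        assert compound_mass_per_mt(1000.0, 1.0) == pytest.approx(1.0)

    def test_iodine_via_potassium_iodate(self):
        # 30 mg/kg iodine needs ~50.6 g KIO3 per MT of salt
        assert compound_mass_per_mt(30.0, IODINE_IN_KIO3) == pytest.approx(0.0506, abs=2e-4)

    def test_folic_acid_direct(self):
        assert compound_mass_per_mt(17.2, 1.0) == pytest.approx(0.0172)

    def test_nonpositive_fraction_rejected(self):
        with pytest.raises(ValueError):
            compound_mass_per_mt(30.0, 0.0)


class TestSprayedCost:
    def test_empty_sprayed_set_costs_nothing(self):
        std = FortificationStandard(program_id="iodized", concentrations={"iodine": 30.0})
        spec = PremixSpec(sprayed_nutrients=[], shipping_handling_per_mt_salt=2.0)
        assert sprayed_premix_cost_per_mt(std, spec, catalog()) == 0.0

    def test_iodine_only_arithmetic(self):
        std = FortificationStandard(program_id="iodized", concentrations={"iodine": 30.0})
        spec = PremixSpec(sprayed_nutrients=["iodine"])
        # 0.030/0.5931 kg KIO3 × 20 USD/kg
        assert sprayed_premix_cost_per_mt(std, spec, catalog()) == pytest.approx(1.012, abs=0.01)

    def test_linearity_in_prices(self):
        std = FortificationStandard(
            program_id="dual", concentrations={"iodine": 30.0, "folic_acid": 17.2}
        )
        spec = PremixSpec(sprayed_nutrients=["iodine", "folic_acid"])
        once = sprayed_premix_cost_per_mt(std, spec, catalog(20.0, 90.0))
        twice = sprayed_premix_cost_per_mt(std, spec, catalog(40.0, 180.0))
        assert twice == pytest.approx(2 * once)

    def test_missing_catalog_entry_names_nutrient(self):
        std = FortificationStandard(
            program_id="dual", concentrations={"iodine": 30.0, "folic_acid": 17.2}
        )
        spec = PremixSpec(sprayed_nutrients=["iodine", "folic_acid"])
        with pytest.raises(ValueError, match="folic_acid"):
            sprayed_premix_cost_per_mt(std, spec, catalog()[:1])


class TestExtrudedCost:
    def test_no_extruded_means_zero(self):
        spec = PremixSpec(sprayed_nutrients=["iodine"])
        assert extruded_premix_cost_per_mt(spec) == 0.0

    def test_inclusion_times_price(self):
        spec = PremixSpec(
            sprayed_nutrients=["iodine"],
            extruded_nutrients=["folic_acid", "vitamin_b12"],
            extruded_inclusion_rate_kg_per_mt=10.0,
            extruded_price_per_kg=4.0,
        )
        assert extruded_premix_cost_per_mt(spec) == pytest.approx(40.0)

    def test_route_split_conserves_total(self):
        std = FortificationStandard(
            program_id="triple",
            concentrations={"iodine": 30.0, "folic_acid": 17.2, "vitamin_b12": 0.39},
        )
        spec = PremixSpec(
            sprayed_nutrients=["iodine"],
            extruded_nutrients=["folic_acid", "vitamin_b12"],
            extruded_inclusion_rate_kg_per_mt=15.0,
            extruded_price_per_kg=4.0,
            shipping_handling_per_mt_salt=1.8,
        )
        breakdown = premix_cost_per_mt(std, spec, catalog())
        assert breakdown.total == pytest.approx(
            breakdown.sprayed + breakdown.extruded + breakdown.shipping
        )
        assert breakdown.shipping == pytest.approx(1.8)


class TestAnnualPremixCost:
    def test_phase_in_year_equals_iodized_book(self, fixture_books):
        dual = fixture_books[("s1", "dual")]
        iodized = fixture_books[("s1", "iodized")]
        for year in (2024, 2025):
            assert annual_premix_cost(dual, year) == pytest.approx(
                annual_premix_cost(iodized, year)
            )

    def test_full_program_year_exceeds_baseline(self, fixture_books):
        dual = fixture_books[("s1", "dual")]
        iodized = fixture_books[("s1", "iodized")]
        assert annual_premix_cost(dual, 2026) > annual_premix_cost(iodized, 2026)

    def test_zero_demand_year_is_zero(self, fixture_books):
        book = fixture_books[("s1", "iodized")].model_copy(deep=True)
        book.demand.__dict__["compliance_fraction"] = 0.0
        assert annual_premix_cost(book, 2026) == 0.0

    def test_per_mt_cost_monotone_across_programs(self, fixture_books):
        for scenario in ("s1", "s2"):
            rates = []
            for program in ("iodized", "dual", "triple", "quad"):
                book = fixture_books[(scenario, program)]
                rates.append(
                    premix_cost_per_mt(book.program, book.premix_spec, book.catalog).total
                )
            assert rates == sorted(rates)

    def test_linear_in_demand(self, fixture_books):
        book = fixture_books[("s1", "triple")]
        doubled = book.model_copy(deep=True)
        doubled.demand.__dict__["population_by_year"] = {
            y: 2 * p for y, p in book.demand.population_by_year.items()
        }
        assert annual_premix_cost(doubled, 2030) == pytest.approx(
            2 * annual_premix_cost(book, 2030)
        )
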