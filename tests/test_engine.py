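"""Cost-report aggregation: per-year totals, averages, shares, incrementals."""

import pytest

from saltcost import (
    activity_cost_in_year,
    annual_fortified_salt_mt,
    compute_report,
    percent_shares,
    random_book,
    share_percent,
)
from saltcost.params import (
    ActivitySchedule,
    Category,
    CostRule,
    Phase,
    Stakeholder,
)


def make_activity(**overrides):
    defaults = dict(
        activity_id="qaqc",
        label="QA/QC",
        phase=Phase.recurring,
        stakeholder=Stakeholder.industry,
        category=Category.refinery_qaqc,
        cost_rule=CostRule(fixed_annual=125_000.0),
        active_years=list(range(2024, 2034)),
    )
    defaults.update(overrides)
    return ActivitySchedule(**defaults)


class TestActivityCostInYear:
    def test_fixed_annual_in_active_year(self, fixture_books):
        book = fixture_books[("s1", "iodized")]
        act = make_activity()
        assert activity_cost_in_year(act, book, 2029) == 125_000.0

    def test_fixed_annual_outside_active_years(self, fixture_books):
        book = fixture_books[("s1", "iodized")]
        act = make_activity(active_years=[2026])
        assert activity_cost_in_year(act, book, 2024) == 0.0

    def test_per_mt_rule_scales_with_demand(self, fixture_books):
        book = fixture_books[("s1", "iodized")]
        act = make_activity(cost_rule=CostRule(per_mt=2.0))
        expected = 2.0 * annual_fortified_salt_mt(book.demand, 2027)
        assert activity_cost_in_year(act, book, 2027) == pytest.approx(expected)

    def test_capital_spreads_eac_over_every_horizon_year(self, fixture_books):
        book = fixture_books[("s1", "dual")]
        act = make_activity(
            phase=Phase.startup,
            category=Category.relabeling,
            cost_rule=CostRule(capital=10_000.0),
            active_years=[2024, 2025],
        )
        per_year = [activity_cost_in_year(act, book, y) for y in book.years]
        assert all(v == pytest.approx(1172.305, abs=0.01) for v in per_year)

    def test_year_outside_horizon_rejected(self, fixture_books):
        book = fixture_books[("s1", "iodized")]
        with pytest.raises(ValueError, match="horizon"):
            activity_cost_in_year(make_activity(), book, 2040)

    def test_iodized_book_has_no_startup_contribution(self, fixture_books):
        book = fixture_books[("s1", "iodized")]
        assert all(a.phase is Phase.recurring for a in book.activities)


class TestComputeReport:
    def test_iodized_annual_average_total(self, fixture_reports):
        assert fixture_reports[("s1", "iodized")].annual_average_total == pytest.approx(
            2_115_000, abs=1_000
        )

    def test_incremental_vs_self_is_all_zero(self, fixture_books):
        book = fixture_books[("s1", "iodized")]
        base = compute_report(book)
        report = compute_report(book, baseline=base)
        inc = report.incremental_vs_baseline
        assert inc.annual_average_total == pytest.approx(0.0, abs=1e-9)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in inc.per_year_total.values())

    def test_dual_incremental_annual_average(self, fixture_reports):
        inc = fixture_reports[("s1", "dual")].incremental_vs_baseline
        assert inc.annual_average_total == pytest.approx(416_000, abs=1_000)

    def test_horizon_mismatch_with_baseline_rejected(self, fixture_books):
        book = fixture_books[("s1", "dual")].model_copy(deep=True)
        base = compute_report(fixture_books[("s1", "iodized")])
        book.__dict__["horizon_end"] = 2032
        with pytest.raises(ValueError, match="horizon"):
            compute_report(book, baseline=base)

    @pytest.mark.parametrize("seed", range(8))
    def test_conservation_per_year_on_random_books(self, seed):
        """Per-year activity costs sum exactly to the per-year total."""
        book = random_book(seed, size=5 + seed * 3)
        report = compute_report(book)
        for y in book.years:
            parts = sum(report.per_year_by_activity[a][y] for a in report.per_year_by_activity)
            assert parts == report.per_year_total[y]

    def test_group_partition_sums_to_total(self, fixture_reports):
        for report in fixture_reports.values():
            assert sum(report.by_group.values()) == pytest.approx(
                report.annual_average_total, abs=1.0
            )
            assert sum(report.by_group_share.values()) == pytest.approx(100.0, abs=0.5)

    def test_by_activity_sums_to_total(self, fixture_reports):
        for report in fixture_reports.values():
            total = sum(r.annual_average for r in report.by_activity.values())
            assert total == pytest.approx(report.annual_average_total, abs=1.0)

    def test_linearity_in_monetary_inputs(self):
        book = random_book(3, size=10)
        scaled = book.model_copy(deep=True)
        k = 3.0
        for act in scaled.activities:
            rule = act.cost_rule
            if rule.fixed_annual is not None:
                rule.fixed_annual = rule.fixed_annual * k
            elif rule.capital is not None:
                rule.capital = rule.capital * k
            elif rule.per_mt is not None:
                rule.per_mt = rule.per_mt * k
        for entry in scaled.catalog:
            entry.price_per_kg_compound = entry.price_per_kg_compound * k
        for spec in (scaled.premix_spec, scaled.baseline_premix_spec):
            if spec is not None:
                spec.extruded_price_per_kg = spec.extruded_price_per_kg * k
                spec.shipping_handling_per_mt_salt = spec.shipping_handling_per_mt_salt * k
        r0, r1 = compute_report(book), compute_report(scaled)
        assert r1.annual_average_total == pytest.approx(k * r0.annual_average_total)
        assert r1.annual_average_per_mt == pytest.approx(k * r0.annual_average_per_mt)

    def test_phase_in_years_match_baseline_plus_annualized_startup(
        self, fixture_books, fixture_reports
    ):
        """Years 1-2 of an expansion book cost the iodized program plus the
        equivalent annual cost of its start-up outlays."""
        for scenario in ("s1", "s2"):
            base = fixture_reports[(scenario, "iodized")]
            for program in ("dual", "triple", "quad"):
                book = fixture_books[(scenario, program)]
                report = fixture_reports[(scenario, program)]
                startup_eac = sum(
                    report.per_year_by_activity[a.activity_id][book.years[0]]
                    for a in book.activities
                    if a.phase is Phase.startup
                )
                for year in book.phase_in_calendar_years:
                    assert report.per_year_total[year] == pytest.approx(
                        base.per_year_total[year] + startup_eac
                    )

    def test_monotone_program_ordering(self, fixture_reports):
        for scenario in ("s1", "s2"):
            totals = [
                fixture_reports[(scenario, p)].annual_average_total
                for p in ("iodized", "dual", "triple", "quad")
            ]
            assert totals == sorted(totals)
            assert totals[0] < totals[1] < totals[2] < totals[3]

    def test_fortifiable_denominator_lowers_per_mt(self, fixture_books):
        book = fixture_books[("s1", "iodized")]
        fortified = compute_report(book, per_mt_denominator="fortified")
        fortifiable = compute_report(book, per_mt_denominator="fortifiable")
        assert fortifiable.annual_average_per_mt == pytest.approx(
            fortified.annual_average_per_mt * 0.89
        )


class TestPercentShares:
    def test_rule_rounds_to_nearest_whole(self):
        assert share_percent(1_002_000, 2_115_000) == 47
        assert share_percent(16_432_000, 18_009_000) == 91

    def test_below_half_percent_rounds_down_to_zero(self):
        assert share_percent(0.4, 100.0) == 0
        assert share_percent(0.6, 100.0) == 1

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            share_percent(1.0, 0.0)

    def test_fixture_shares_match_published_rows(self, fixture_reports):
        report = percent_shares(fixture_reports[("s1", "iodized")])
        shares = report.rounded_shares
        assert shares["premix"] == 47
        assert shares["refinery_fortification"] == 26
        assert shares["refinery_qaqc"] == 6
        assert shares["refinery_admin"] == 16
        assert shares["social_marketing"] == 0  # 0.43% floors to 0
        assert shares["gov_refinery_monitoring"] == 0  # 0.38%
        assert shares["gov_household_monitoring"] == 1  # 0.66%
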