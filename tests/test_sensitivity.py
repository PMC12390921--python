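"""±fraction sensitivity: symmetry, ordering, and component isolation."""

import pytest

from saltcost import SensitivitySpec, compute_report, random_book, run_sensitivity
from saltcost.sensitivity import ALL_COMPONENTS, COMPONENT_CATEGORIES, scaled_book


def test_spec_rejects_empty_components_and_bad_fraction():
    with pytest.raises(ValueError):
        SensitivitySpec(varied_components=())
    with pytest.raises(ValueError):
        SensitivitySpec(fraction=0.0)
    with pytest.raises(ValueError):
        SensitivitySpec(fraction=1.0)
    with pytest.raises(ValueError, match="unknown"):
        SensitivitySpec(varied_components=("qa_qc_cost",))


@pytest.mark.parametrize("scenario,program", [("s1", "dual"), ("s1", "quad"), ("s2", "triple")])
def test_symmetry_base_minus_low_equals_high_minus_base(fixture_books, scenario, program):
    """The model is linear in each component's prices, so ± variation is symmetric."""
    result = run_sensitivity(fixture_books[(scenario, program)], SensitivitySpec())
    for low, base, high in result.one_way.values():
        assert base - low == pytest.approx(high - base, rel=1e-9, abs=1e-12)


def test_ordering_best_below_all_lows_worst_above_all_highs(fixture_books):
    result = run_sensitivity(fixture_books[("s1", "dual")], SensitivitySpec())
    for low, base, high in result.one_way.values():
        assert result.best_case_per_mt <= low <= base <= high <= result.worst_case_per_mt


def test_one_way_swing_equals_fraction_times_component_share(fixture_books):
    """high − base = f × (component's per-MT cost), by linearity."""
    book = fixture_books[("s1", "triple")]
    f = 0.30
    result = run_sensitivity(book, SensitivitySpec(fraction=f))
    base_report = compute_report(book)
    n = len(book.years)
    for component, categories in COMPONENT_CATEGORIES.items():
        component_avg = sum(
            res.annual_average
            for res in base_report.by_activity.values()
            if res.category in {c.value for c in categories}
        )
        component_per_mt = component_avg / base_report.mean_fortified_mt
        low, base, high = result.one_way[component]
        assert high - base == pytest.approx(f * component_per_mt, rel=1e-9)


@pytest.mark.parametrize("seed", [2, 11])
def test_worst_minus_best_from_brute_force_on_random_book(seed):
    """worst − best = 2f × Σ varied per-MT costs, cross-checked by summing
    the independently recomputed one-way swings."""
    book = random_book(seed, size=14)
    f = 0.30
    result = run_sensitivity(book, SensitivitySpec(fraction=f))
    swing_sum = sum(high - low for low, _b, high in result.one_way.values())
    assert result.worst_case_per_mt - result.best_case_per_mt == pytest.approx(
        swing_sum, rel=1e-9, abs=1e-12
    )


def test_fraction_zero_limit_collapses():
    book = random_book(5, size=8)
    tiny = run_sensitivity(book, SensitivitySpec(fraction=1e-12))
    for low, base, high in tiny.one_way.values():
        assert low == pytest.approx(base, rel=1e-9)
        assert high == pytest.approx(base, rel=1e-9)


def test_non_varied_activities_bit_identical(fixture_books):
    book = fixture_books[("s1", "dual")]
    varied = scaled_book(book, {"refinery_fortification_cost": 1.3})
    r0, r1 = compute_report(book), compute_report(varied)
    varied_categories = {"refinery_fortification"}
    for act_id, series in r0.per_year_by_activity.items():
        if r0.by_activity[act_id].category in varied_categories:
            continue
        assert r1.per_year_by_activity[act_id] == series


def test_market_monitoring_excluded_from_government_component(fixture_books):
    book = fixture_books[("s1", "dual")]
    varied = scaled_book(book, {"government_monitoring_cost": 1.3})
    r0, r1 = compute_report(book), compute_report(varied)
    assert (
        r1.per_year_by_activity["gov_market_monitoring"]
        == r0.per_year_by_activity["gov_market_monitoring"]
    )
    assert (
        r1.by_activity["gov_refinery_monitoring"].annual_average
        > r0.by_activity["gov_refinery_monitoring"].annual_average
    )


def test_premix_component_includes_potassium_iodate(fixture_books):
    """Varying premix price must move the iodized book too (iodate is premix)."""
    book = fixture_books[("s1", "iodized")]
    result = run_sensitivity(
        book, SensitivitySpec(varied_components=("premix_price",))
    )
    low, base, high = result.one_way["premix_price"]
    assert high > base > low


def test_all_components_default(fixture_books):
    result = run_sensitivity(fixture_books[("s1", "quad")], SensitivitySpec())
    assert set(result.one_way) == set(ALL_COMPONENTS)
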