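"""Building a parameter book from unit-level inputs.

Shows the workflow the calibrated fixture skips: normalising historical
amounts to base-year USD, annualising an equipment purchase, and costing a
per-ton line, for a small imaginary two-activity iodization program.  The
printed per-year totals show the equipment's equivalent annual cost spread
over the horizon on top of the demand-driven iodate line.
"""

from saltcost import (
    ActivitySchedule,
    Category,
    CostRule,
    DemandParams,
    FinanceParams,
    FortificationStandard,
    MoneyAmount,
    ParameterBook,
    Phase,
    Stakeholder,
    compute_report,
    to_base_usd,
)

finance = FinanceParams(
    discount_rate=0.03,
    equipment_life_years=10,
    usd_deflator_by_year={2019: 104.7, 2021: 110.2},
    etb_cpi_by_year={2019: 100.0, 2021: 152.8},
    etb_per_usd_base_year=43.7,
)

# a dosing pump quoted at 80,000 USD in 2019 → base-year (2021) USD
pump_2021_usd = to_base_usd(MoneyAmount(80_000, "USD", 2019), finance)
# lab running costs quoted in 2019 Birr
lab_2021_usd = to_base_usd(MoneyAmount(900_000, "ETB", 2019), finance)
print(f"pump (2019 USD 80,000)  -> 2021 USD {pump_2021_usd:,.0f}")
print(f"lab  (2019 ETB 900,000) -> 2021 USD {lab_2021_usd:,.0f}")

years = list(range(2024, 2034))
book = ParameterBook(
    book_id="demo-iodized",
    program=FortificationStandard(program_id="iodized", concentrations={"iodine": 30.0}),
    demand=DemandParams(
        population_by_year={y: 5_000_000 for y in years},
        per_capita_salt_g_per_day=6.0,
        compliance_fraction=0.9,
    ),
    finance=finance,
    activities=[
        ActivitySchedule(
            activity_id="dosing_pump",
            label="Iodate dosing pump (annualized capital)",
            phase=Phase.recurring,
            stakeholder=Stakeholder.industry,
            category=Category.refinery_fortification,
            cost_rule=CostRule(capital=pump_2021_usd),
            active_years=years,
        ),
        ActivitySchedule(
            activity_id="iodate",
            label="Potassium iodate, per ton of fortified salt",
            phase=Phase.recurring,
            stakeholder=Stakeholder.industry,
            category=Category.premix,
            cost_rule=CostRule(per_mt=1.6),
            active_years=years,
        ),
        ActivitySchedule(
            activity_id="lab",
            label="QA/QC laboratory",
            phase=Phase.recurring,
            stakeholder=Stakeholder.industry,
            category=Category.refinery_qaqc,
            cost_rule=CostRule(fixed_annual=lab_2021_usd),
            active_years=years,
        ),
    ],
    horizon_start=2024,
    horizon_end=2033,
)

report = compute_report(book)
print(f"\nannual average total: {report.annual_average_total:,.0f} USD")
for activity_id, res in report.by_activity.items():
    print(f"  {activity_id:<12} {res.annual_average:>12,.0f} USD/yr")
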