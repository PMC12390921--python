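book_id: ethiopia-s2-iodized
scenario: s2
program:
  program_id: iodized
  concentrations:
    iodine: 39.0
demand:
  population_by_year:
    '2024': 125414000.0
    '2025': 128361000.0
    '2026': 131378000.0
    '2027': 134465000.0
    '2028': 137625000.0
    '2029': 140859000.0
    '2030': 144169000.0
    '2031': 147557000.0
    '2032': 151025000.0
    '2033': 154574000.0
  per_capita_salt_g_per_day: 5.0
  compliance_fraction: 0.89
  days_per_year: 365.0
finance:
  discount_rate: 0.03
  equipment_life_years: 10.0
  base_currency_year: 2021
  usd_deflator_by_year:
    '2019': 104.7
    '2020': 105.9
    '2021': 110.2
  etb_cpi_by_year:
    '2019': 100.0
    '2020': 120.4
    '2021': 152.8
  etb_per_usd_base_year: 43.7
activities:
- activity_id: premix
  label: Premix, including shipping and handling
  phase: recurring
  stakeholder: industry
  category: premix
  cost_rule:
    premix_from_spec: true
  active_years:
  - 2024
  - 2025
  - 2026
  - 2027
  - 2028
  - 2029
  - 2030
  - 2031
  - 2032
  - 2033
- activity_id: refinery_fortification
  label: Salt refinery fortification costs (labor, power/fuel, annualized equipment,
    maintenance)
  phase: recurring
  stakeholder: industry
  category: refinery_fortification
  cost_rule:
    fixed_annual: 477000.0
    premix_from_spec: false
  active_years:
  - 2024
  - 2025
  - 2026
  - 2027
  - 2028
  - 2029
  - 2030
  - 2031
  - 2032
  - 2033
- activity_id: refinery_qaqc
  label: Salt refinery fortification QA/QC activities
  phase: recurring
  stakeholder: industry
  category: refinery_qaqc
  cost_rule:
    fixed_annual: 125000.0
    premix_from_spec: false
  active_years:
  - 2024
  - 2025
  - 2026
  - 2027
  - 2028
  - 2029
  - 2030
  - 2031
  - 2032
  - 2033
- activity_id: refinery_internal_training
  label: Salt refinery internal training/retraining
  phase: recurring
  stakeholder: industry
  category: refinery_training
  cost_rule:
    fixed_annual: 22000.0
    premix_from_spec: false
  active_years:
  - 2024
  - 2025
  - 2026
  - 2027
  - 2028
  - 2029
  - 2030
  - 2031
  - 2032
  - 2033
- activity_id: refinery_admin
  label: Salt refinery management, administration, and overhead
  phase: recurring
  stakeholder: industry
  category: refinery_admin
  cost_rule:
    fixed_annual: 312000.0
    premix_from_spec: false
  active_years:
  - 2024
  - 2025
  - 2026
  - 2027
  - 2028
  - 2029
  - 2030
  - 2031
  - 2032
  - 2033
- activity_id: gov_refinery_monitoring
  label: Government inspections and monitoring of salt refineries
  phase: recurring
  stakeholder: government
  category: gov_refinery_monitoring
  cost_rule:
    fixed_annual: 8000.0
    premix_from_spec: false
  active_years:
  - 2024
  - 2025
  - 2026
  - 2027
  - 2028
  - 2029
  - 2030
  - 2031
  - 2032
  - 2033
- activity_id: gov_import_monitoring
  label: Government monitoring of imported salt
  phase: recurring
  stakeholder: government
  category: gov_import_monitoring
  cost_rule:
    fixed_annual: 2000.0
    premix_from_spec: false
  active_years:
  - 2024
  - 2025
  - 2026
  - 2027
  - 2028
  - 2029
  - 2030
  - 2031
  - 2032
  - 2033
- activity_id: gov_market_monitoring
  label: Government monitoring of salt at markets and retail outlets
  phase: recurring
  stakeholder: government
  category: gov_market_monitoring
  cost_rule:
    fixed_annual: 2000.0
    premix_from_spec: false
  active_years:
  - 2024
  - 2025
  - 2026
  - 2027
  - 2028
  - 2029
  - 2030
  - 2031
  - 2032
  - 2033
- activity_id: gov_household_monitoring
  label: Government household monitoring
  phase: recurring
  stakeholder: government
  category: gov_household_monitoring
  cost_rule:
    fixed_annual: 14000.0
    premix_from_spec: false
  active_years:
  - 2024
  - 2025
  - 2026
  - 2027
  - 2028
  - 2029
  - 2030
  - 2031
  - 2032
  - 2033
- activity_id: social_marketing
  label: Social marketing/advocacy
  phase: recurring
  stakeholder: government
  category: social_marketing
  cost_rule:
    fixed_annual: 9000.0
    premix_from_spec: false
  active_years:
  - 2024
  - 2025
  - 2026
  - 2027
  - 2028
  - 2029
  - 2030
  - 2031
  - 2032
  - 2033
- activity_id: gov_capacity_building
  label: Capacity building/training for food control agency personnel
  phase: recurring
  stakeholder: government
  category: gov_capacity_building
  cost_rule:
    fixed_annual: 14000.0
    premix_from_spec: false
  active_years:
  - 2024
  - 2025
  - 2026
  - 2027
  - 2028
  - 2029
  - 2030
  - 2031
  - 2032
  - 2033
- activity_id: gov_admin
  label: Government management, administration, and overhead
  phase: recurring
  stakeholder: government
  category: gov_admin
  cost_rule:
    fixed_annual: 24000.0
    premix_from_spec: false
  active_years:
  - 2024
  - 2025
  - 2026
  - 2027
  - 2028
  - 2029
  - 2030
  - 2031
  - 2032
  - 2033
horizon_start: 2024
horizon_end: 2033
phase_in_years: 0
premix_spec:
  sprayed_nutrients:
  - iodine
  extruded_nutrients: []
  extruded_inclusion_rate_kg_per_mt: 0.0
  extruded_price_per_kg: 0.0
  shipping_handling_per_mt_salt: 2.341991331993713
  overage_fraction: 0.0
catalog:
- nutrient: iodine
  compound: potassium iodate
  nutrient_mass_fraction: 0.5930087709870515
  price_per_kg_compound: 30.0
- nutrient: folic_acid
  compound: folic acid
  nutrient_mass_fraction: 1.0
  price_per_kg_compound: 90.0
notes: 'Calibrated Ethiopia fixture: activity-level annual costs encode published
  table rows; see the fixture manifest.'
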