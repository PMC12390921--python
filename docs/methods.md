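# Methods

## Model

`saltcost` implements a deterministic, activity-based costing model for
large-scale salt fortification programs, evaluated from a societal
perspective (all costs counted regardless of payer) over a fixed calendar
horizon. A program × scenario is described entirely by a parameter book;
the engine is a pure function of the book, which makes every result
reproducible and every sensitivity analysis a re-run on a transformed book.

Each activity carries exactly one cost rule:

- `fixed_annual` — a base-year USD amount in each of its active years;
- `capital` — a lump sum converted to an equivalent annual cost
  `EAC = K·r/(1−(1+r)^(−L))` and spread over every horizon year (the
  expenditure occurs during phase-in; the cost accrues over the asset's
  life). At `r = 0` the straight-line limit `K/L` is used;
- `per_mt` — a USD rate per metric ton of fortified salt, multiplied by the
  year's demand;
- `premix_from_spec` — the premix line, computed from the book's premix
  specification and demand (see below).

Annual averages are plain arithmetic means of per-year totals,
undiscounted; discounting enters only through the EAC. This mirrors how
program costing studies in this field print their tables. Start-up
(non-equipment) expansion outlays are annualized over the full horizon at
the same rate as equipment; at the magnitudes involved (≤ 3,000 USD/yr)
the alternative conventions differ by less than the tables' rounding unit.

### Demand

Fortified tonnage in year *t* is
`Q_t = P_t × g × d / 10⁶ × c`: population × per-capita
discretionary-plus-manufactured salt (g/day) × days per year (default 365),
converted to MT, times the compliance fraction (share of the salt supply
actually fortified to standard). The per-capita values already fold in the
~90 % share of intake that is fortifiable, so no separate factor appears.
Per-MT unit costs use mean fortified tonnage by default; a `fortifiable`
denominator (no compliance factor) is exposed because published per-MT rows
do not state their convention.

### Premix

Sprayed fortificants: compound mass per MT is `conc(mg/kg) / 1000 / f`
(mg/kg ≡ g/MT), where `f` is the nutrient mass fraction of the compound
(iodine in potassium iodate: 126.904/214.001 ≈ 0.593), times a catalog
price per kg, times `1 + overage` (overage defaults to 0: the relevant
nutrients are stable in refined salt, so no deliberate excess is modelled).
Extruded, encapsulated premix is costed as a delivered black box —
inclusion rate (kg premix per MT salt) × price per kg — rather than
rebuilding carrier/extrusion economics, because only delivered-price
estimates exist for it. A shipping/handling adder per MT of salt is split
across routes in proportion to fortificant cost. No premix taxes are
modelled (Ethiopia levies none).

### Phasing and incrementals

Expansion books have a 2-year phase-in during which the baseline
iodization program continues: the book stores a baseline (iodine-only)
premix spec used by the premix line in those years, and recurring
activities whose level changes at full program are split into a phase-in
segment (baseline level) and a full-program segment. Start-up activities
are only active during phase-in. Incremental results are metric-wise
differences against a baseline report computed on the same horizon.

### Percent shares

Shares are `100 × component / total`, rounded to the nearest whole
percent, except that components below 0.5 % of total round down to 0 % —
the convention used in the published tables this package reproduces.

### Sensitivity

Three uncertain components can be varied by ±fraction (default 30 %):
premix price (catalog prices including potassium iodate, extruded premix
price, shipping), refinery fortification cost (the fortification line
only, not QA/QC, training or administration), and government monitoring
(refinery, import and household monitoring; market monitoring is excluded
because the published component description names only those three — the
mapping is overridable). Each variation deep-copies and re-runs the whole
engine; because the model is linear in these inputs, the exact symmetry
`base − low = high − base` and the identity
`worst − best = 2f × Σ(component per-MT costs)` act as independent checks
on the implementation, and the tests assert them.

## The Ethiopia fixture

The fixture emulates the conditions of the published Ethiopia costing
study: 2024–2033 horizon, 2021 USD, 89 % compliance, 3 % discount rate,
10-year equipment life, fortification standards of 30 mg/kg iodine,
17.2 mg/kg folic acid, 0.39 mg/kg vitamin B-12 and 600 mg/kg zinc under
current consumption (6.7 g/d), and 39 / 23.4 / 0.39 / 800 mg/kg under a
reduced-consumption scenario (5 g/d).

The study's unit-level inputs (interview-derived personnel and supply
costs) were never published; what is published is the complete
activity-level table of 10-year annual averages. The fixture therefore
calibrates at the activity level:

- recurring rows are entered as `fixed_annual` amounts, with expansion
  rows split so that 2 phase-in years at the baseline level plus 8
  full-program years average exactly to the published cell;
- start-up rows are entered as capital lump sums whose EAC equals the
  published annualized values;
- the premix line is driven by the premix module with fortificant prices
  fixed once at realistic market values (potassium iodate 30 USD/kg, folic
  acid 90 USD/kg, extruded inclusion 15 kg/MT for triple and 20 kg/MT for
  quadruple) and one closing parameter per book — the shipping adder
  (iodized, dual) or the delivered extruded price (triple, quadruple) —
  solved linearly so the 10-year average premix cost equals the published
  row. The resulting delivered extruded prices (≈ 3–5.5 USD/kg) and the
  implied folic-acid increment are mutually consistent across scenarios,
  which is a useful plausibility check on the calibration.

The population series is an explicit, replaceable table: an exponential
trajectory (~125.4 M in 2024, +2.35 %/yr) consistent with the medium-variant
World Population Prospects outlook for Ethiopia, whose level was chosen
once so that mean fortified tonnage under current consumption is
~303,700 MT/yr, putting the iodized program at ~7.0 USD/MT. Because the
study's exact population/demand series is unpublished, per-capita and
per-MT values are calibration-level reproductions (they match published
values under current consumption; the reduced-consumption per-MT values sit
~0.5 % high), and no golden test targets them.

Two published aggregates are internally inconsistent with their own
printed activity columns: the reduced-consumption dual program total
(printed 2,410,000; its rows sum to 2,412,000) and, within the rounding
unit, the reduced-consumption quadruple total (printed 18,318,000; rows
sum 18,317,000). The fixture treats the printed rows as authoritative, so
the engine reproduces the column sums; the manifest records both values
and flags the > 1,000 USD case. Published premix-per-MT rows and the
published sensitivity extremes use denominator conventions that cannot be
recovered from the printed data; they are stored as informational
annotations, reported by the acceptance script, but not asserted.

### What the fixture does and does not show

Passing golden tests demonstrates that the aggregation, phasing, capital
annualization, incremental and share logic reproduce the published
aggregates from activity-level inputs. They do not validate the
unpublished unit costs, the premix market prices, or transferability to
other countries — the fixture is a calibration, not primary data.
Unit-level workflows (currency normalisation, per-MT rules, capital items)
are exercised by the random-book generator and `examples/custom_book.py`
instead.

## Numerical choices and degenerate inputs

- All arithmetic is unrounded `float64`; rounding (nearest 1,000 USD for
  totals, one decimal for per-MT) applies only to display output.
- `share_percent` uses floor(x + 0.5) (round-half-up) plus the < 0.5 → 0
  floor; a zero total raises.
- Zero demand or zero compliance produce zero premix and per-MT costs
  without error; a missing population or index year raises an error naming
  the year.
- Equality of books is field-wise; YAML round-trips preserve floats
  exactly (pyyaml writes full-precision reprs).
- Sensitivity runs validate the low ≤ base ≤ high ordering internally and
  raise if violated.

## Problem sizes

The model is tiny by construction: 8 books × ~20 activities × 10 years.
The full test suite (including 30 fuzzed random books and
hypothesis-driven property tests) and the acceptance script each run in a
few seconds on one CPU.

## Known limitations

- Single national compliance fraction; no salt-market segmentation,
  import/domestic split, or lower-quality artisanal salt stream.
- Extruded premix is a delivered price, not an ingredient-level model; the
  published fortificant shares of premix cost (24 % triple, 54 % quad) are
  carried as annotations only.
- No cost-effectiveness or cost-benefit layer, no consumer-price
  pass-through, no probabilistic (Monte Carlo) sensitivity — the
  sensitivity design is strictly deterministic ±fraction.
- Outputs are base-year USD only; nominal local-currency projections are
  out of scope.
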