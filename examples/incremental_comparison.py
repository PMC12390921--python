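"""Incremental cost of expanding iodization to multi-nutrient fortification.

Runs all four current-consumption program books (iodized baseline; dual adds
folic acid; triple adds vitamin B-12 via extruded premix; quadruple adds
zinc) and prints each program's annual average total, its increment over the
baseline, and cost per MT of fortified salt.  The jump from dual to triple
reflects the switch from spraying fortificants to blending imported
extruded, encapsulated premix, which dominates program cost (>90%).
"""

from saltcost import build_ethiopia_fixture, compute_report

books, _ = build_ethiopia_fixture()
base = compute_report(books[("s1", "iodized")])

print(f"{'program':<10}{'avg USD/yr':>14}{'incremental':>14}{'USD/MT':>9}")
for program in ("iodized", "dual", "triple", "quad"):
    report = compute_report(
        books[("s1", program)], baseline=None if program == "iodized" else base
    )
    inc = report.incremental_vs_baseline
    inc_str = f"{inc.annual_average_total:>14,.0f}" if inc else f"{'—':>14}"
    print(
        f"{program:<10}{report.annual_average_total:>14,.0f}{inc_str}"
        f"{report.annual_average_per_mt:>9.1f}"
    )
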