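"""±30% sensitivity on the dual-fortified-salt program (current consumption).

Varies premix price (including potassium iodate), refinery fortification
cost, and government monitoring cost one at a time and together, re-running
the full engine each time, and prints the resulting annual average cost per
MT of fortified salt.  Premix price dominates the swing; the best/worst rows
vary all three components simultaneously.
"""

from saltcost import SensitivitySpec, ethiopia_book, run_sensitivity

book = ethiopia_book("dual", scenario="s1")
result = run_sensitivity(book, SensitivitySpec(fraction=0.30))

print(f"base: {result.base_per_mt:.2f} USD/MT of fortified salt")
print(f"{'component':<32}{'low':>8}{'base':>8}{'high':>8}")
for component, (low, base, high) in result.one_way.items():
    print(f"{component:<32}{low:>8.2f}{base:>8.2f}{high:>8.2f}")
print(f"{'best case (all -30%)':<32}{result.best_case_per_mt:>8.2f}")
print(f"{'worst case (all +30%)':<32}{'':>16}{result.worst_case_per_mt:>8.2f}")
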