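"""Rescue-primer design for leftover variants, with Tm ranges.

After refinement some site variants remain uncovered (they would need
simultaneous widening at several positions).  Rescue design clusters them
by Hamming distance and emits one minimal degenerate consensus per
cluster; each primer is tagged with its first three bases, and each oligo
gets a Wallace-rule melting-temperature range over its expansions.
"""

from primeraudit import (
    RefineConfig,
    VariantTable,
    design_rescue,
    refine_greedy,
    tm_range,
)

table = VariantTable.from_counts(
    {
        "GTGAATCATCGAATCTTTGAA": 900,   # covered by the seed
        "GCGAATCATCGAATCTTTGAA": 50,    # two variants differing near the 5' end...
        "GCGAGTCATCGAATCTTTGAA": 43,    # ...within Hamming distance 2 of each other
        "CTGAATCATCAAATCTTTGAA": 7,     # a second, distant cluster
    },
    primer_name="ITS86F-like",
)

result = refine_greedy("GTGAATCATCGAATCTTTGAA", table, RefineConfig(target_coverage_pct=90))
print(f"refined {result.refined}: {result.final.rate_pct}% "
      f"(Tm {tm_range(result.refined, 'wallace')} °C, Wallace)")

for p in design_rescue(result.final.uncovered, max_primers=2, radius=2):
    covered = sum(v.count for v in p.cluster)
    print(f"rescue -{p.name_suffix}: {p.sequence}  covers {covered} leftover sites "
          f"(Tm {tm_range(p.sequence, 'wallace')} °C)")

print("\nThe rescue consensus unions the observed bases per position, so it covers")
print("every variant in its cluster; together with the refined primer the whole")
print("table is amplifiable.")
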