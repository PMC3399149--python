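"""Diversity arithmetic on the shipped survey summary tables.

Recomputes the concatenated group diversities from per-locus values, the
wild-to-cultivated diversity reduction, and Tajima's D for one locus from
its printed summary row.
"""

from flaxpopgen import concatenated_pi, percent_reduction, tajimas_d_from_summary
from flaxpopgen.datasets import GROUP_TABLES, GROUP_TOTALS, LOCI

for group in ("fiber", "winter"):
    tab = GROUP_TABLES[group]
    per_locus = [(tab.loc[l, "pi"], tab.loc[l, "L"]) for l in LOCI]
    print(f"{group:>7} concatenated pi = {concatenated_pi(per_locus):.4f}")

pale, cult = GROUP_TOTALS["pale"]["pi"], GROUP_TOTALS["cultivated"]["pi"]
print(f"wild {pale} vs cultivated {cult}: {percent_reduction(pale, cult)}% reduction")

# pale-flax locus 449B/A: n=10 sequences, S=2, pi=0.0043 over 248 bp
D = tajimas_d_from_summary(10, 2, 0.0043 * 248)
print(f"Tajima's D for pale 449B/A from its summary row: {D:.3f}")
print(
    "The weighted means are the 'Total' rows of the per-group tables; a\n"
    "positive D here means intermediate-frequency variants exceed the\n"
    "neutral expectation for this locus, though not significantly."
)
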