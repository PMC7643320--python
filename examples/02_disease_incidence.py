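"""Disease-incidence arm: parse the packaged 41-animal F3 pesticide-lineage
disease table, derive per-animal totals and multiple-disease flags, and print
the incidence summary (positives / evaluable animals, whole-percent).

Animals with an n/a entry for a tissue are excluded from that tissue's
denominator, which is why testis is /40 and late puberty /37.
"""

from epidmr import incidence_summary, load_f3_disease_table
from epidmr.pathology import compare_incidence

table = load_f3_disease_table()
print(f"{len(table)} animals; first rows:")
print(table.head(5).to_string(index=False))

inc = incidence_summary(table)
print("\nincidence (positives / evaluable = percent):")
for _, row in inc.iterrows():
    print(f"  {row['pathology']:<18} {row['n_positive']:>2}/"
          f"{row['n_evaluable']} = {row['percentage']}%")

# Fisher exact comparison of testis incidence against a hypothetical
# low-incidence control group (1 of 40)
p = compare_incidence(14, 40, 1, 40)
print(f"\nFisher exact, testis 14/40 vs control 1/40: p = {p:.2e}")
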