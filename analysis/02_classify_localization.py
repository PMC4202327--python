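"""Classify localization divergence for the 19 relocalized duplicate pairs.

Compares the two compartment sets of each pair: disjoint sets are complete
changes, overlapping-but-unequal sets are expansions/contractions.  The
classified table and the summary split are written to results/.
"""

from pathlib import Path

from dupreloc.stats import classify_table, load_relocalized_pairs

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

table = classify_table(load_relocalized_pairs())
table.to_csv(OUT / "localization_calls.tsv", sep="\t", index=False)

counts = table["call"].value_counts()
print(table[["gene1", "scl1", "gene2", "scl2", "call"]].to_string(index=False))
print(f"\ncomplete changes: {counts.get('complete_change', 0)}; "
      f"expansion/contraction: {counts.get('partial_change', 0)}")
print(f"wrote {OUT / 'localization_calls.tsv'}")
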