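"""Thresholded cross-drug DEG intersection within each drug category.

Admits categories with >= 6 drugs, retains genes present in >= 70 % of a
category's per-drug DEG lists, and exports occurrence tables plus
UpSet-style exclusive-intersection counts under results/intersect/.
"""

import json

import pandas as pd

from common import RUN_CFG, results_dir
from resistome.de import deg_gene_set
from resistome.intersect import filter_categories, occurrence_table, upset_counts
from resistome.io import read_catalog

inputs = results_dir("inputs")
de_dir = results_dir("de")
out = results_dir("intersect")

catalog = read_catalog(inputs / "catalog.tsv")
deg = {p.stem: deg_gene_set(pd.read_csv(p, sep="\t")) for p in de_dir.glob("*.tsv")}
admitted = filter_categories(catalog, RUN_CFG.min_drugs_per_category,
                             usable_drugs=set(deg))
print(f"admitted {len(admitted)} of {len(catalog.categories)} categories "
      f"(>= {RUN_CFG.min_drugs_per_category} drugs)")

for cat, drugs in admitted.items():
    lists = {d: deg[d] for d in drugs}
    table = occurrence_table(lists, RUN_CFG.intersect_frac)
    table.to_csv(out / f"{cat}.tsv", sep="\t", index=False)
    counts = upset_counts(lists)
    (out / f"{cat}_upset.json").write_text(json.dumps(
        {"|".join(sorted(sig)): n for sig, n in sorted(counts.items(),
                                                       key=lambda kv: -kv[1])},
        indent=1))
    strict = [g for g, row in table.set_index("gene").iterrows()
              if row["occurrence"] == len(drugs)]
    kept = int(table["retained"].sum())
    print(f"{cat}: {kept} genes at the 70% threshold "
          f"(required {table.attrs['required']}/{len(drugs)} lists); "
          f"strict intersection across all drugs: {len(strict)} genes")
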