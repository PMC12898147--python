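"""Per-drug resistant-vs-sensitive differential expression.

Reads results/inputs/, writes one DEG table per drug under results/de/,
and reports how many genes pass |log2FC| >= 1 and padj < 0.05 per drug.
"""

from common import RUN_CFG, results_dir
from resistome.de import run_de
from resistome.io import read_expression, read_sensitivity

inputs = results_dir("inputs")
out = results_dir("de")
expr = read_expression(inputs / "expression.tsv")
sens = read_sensitivity(inputs / "sensitivity.tsv")

for drug in sens.drugs:
    table = run_de(expr, sens, drug, RUN_CFG)
    table.to_csv(out / f"{drug}.tsv", sep="\t", index=False)
    n_sig = int(table["significant"].sum())
    n_up = int((table["significant"] & (table["direction"] > 0)).sum())
    print(f"{drug}: {n_sig} significant genes ({n_up} up, {n_sig - n_up} down)")
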