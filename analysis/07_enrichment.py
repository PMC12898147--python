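"""Gene-set over-representation of each category's core genes.

Hypergeometric ORA of the consensus core genes against the GMT collection,
with the expression matrix's genes as the universe. Writes one result
table per category under results/enrich/.
"""

import json

from common import results_dir
from resistome.enrich import run_ora
from resistome.io import read_expression, read_gmt

inputs = results_dir("inputs")
sel_dir = results_dir("select")
out = results_dir("enrich")

expr = read_expression(inputs / "expression.tsv")
gmt = read_gmt(inputs / "gene_sets.gmt")
core_genes = json.loads((sel_dir / "core_genes.json").read_text())
universe = set(expr.gene_ids)

for cat, genes in sorted(core_genes.items()):
    res = run_ora(set(genes), gmt, universe=universe)
    res.to_csv(out / f"{cat}.tsv", sep="\t", index=False)
    top = res.iloc[0]
    print(f"{cat}: top set {top['set_id']} "
          f"(k={top['k']}/{top['K']}, p={top['pvalue']:.3g}, "
          f"padj={top['padj']:.3g}, fold={top['fold_enrichment']:.1f})")
    n_sig = int(res["significant"].sum())
    print(f"  {n_sig} of {len(res)} sets at p < 0.05")
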