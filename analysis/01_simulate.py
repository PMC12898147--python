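"""Generate the synthetic DepMap-like input bundle with planted ground truth.

Writes expression.tsv, sensitivity.tsv, catalog.tsv, ppi.tsv,
gene_sets.gmt, and ground_truth.json under results/inputs/.
"""

import json

from common import RUN_CFG, SYN_CFG, results_dir
from resistome.pipeline import simulate_inputs

out = results_dir("inputs")
info = simulate_inputs(SYN_CFG, out, RUN_CFG.seed)
truth = json.loads((out / "ground_truth.json").read_text())
print(f"wrote inputs to {out}")
print(f"  {SYN_CFG.n_cell_lines} cell lines x {info['n_genes']} genes, "
      f"{info['n_drugs']} drugs in {SYN_CFG.n_categories} categories")
for cat, genes in truth["planted_core_genes"].items():
    print(f"  {cat}: core genes {genes}, "
          f"{len(truth['consensus_drugs'][cat])} consensus drugs, "
          f"{len(truth['minority_drugs'][cat])} minority drugs")
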