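"""PPI-topology core genes per category and overlap with the ML route.

Selects genes present in >= 60 % of a category's DEG lists, induces the
PPI subnetwork (score >= 0.4), and calls genes with betweenness strictly
above the subnetwork median as core. Writes node tables and overlap
reports under results/network/.
"""

import json

import pandas as pd

from common import RUN_CFG, results_dir
from resistome.de import deg_gene_set
from resistome.io import read_catalog, read_edge_list
from resistome.network import analyze_category, overlap_report

inputs = results_dir("inputs")
de_dir = results_dir("de")
sel_dir = results_dir("select")
out = results_dir("network")

catalog = read_catalog(inputs / "catalog.tsv")
edges = read_edge_list(inputs / "ppi.tsv")
deg = {p.stem: deg_gene_set(pd.read_csv(p, sep="\t")) for p in de_dir.glob("*.tsv")}
core_genes = json.loads((sel_dir / "core_genes.json").read_text())

for cat in sorted(core_genes):
    lists = {d: deg[d] for d in catalog.categories[cat]}
    result = analyze_category(cat, lists, edges, frac=RUN_CFG.ppi_frac,
                              min_score=RUN_CFG.min_ppi_score)
    result.nodes.to_csv(out / f"{cat}_nodes.tsv", sep="\t", index=False)
    rep = overlap_report(result.core_genes(), set(core_genes[cat]))
    (out / f"{cat}_overlap.json").write_text(json.dumps(rep, indent=1, sort_keys=True))
    print(f"{cat}: {len(result.nodes)} nodes, median betweenness "
          f"{result.median_betweenness:.2f}, core genes {rep['network_core']}")
    print(f"  overlap with ML core genes: {rep['intersection']} "
          f"(Jaccard {rep['jaccard']:.2f})")
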