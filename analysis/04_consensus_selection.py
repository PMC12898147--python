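"""Three-method consensus ranking of each category's retained genes.

For one representative drug per distinct label pattern in each category,
ranks the 70 %-retained genes by random-forest Gini importance, GA
inclusion frequency, and RFE elimination order, then averages the ranks.
Writes consensus tables under results/select/ and records the top-k
(k = 5) core genes per category in results/select/core_genes.json.
"""

import json

import pandas as pd

from common import RUN_CFG, results_dir
from resistome.io import read_catalog, read_expression, read_sensitivity
from resistome.pipeline import stage_seed
from resistome.selection import (
    aggregate_ranks, build_feature_matrix, ga_select, rf_importance, rfe_rank,
    select_core_genes,
)

inputs = results_dir("inputs")
int_dir = results_dir("intersect")
out = results_dir("select")

expr = read_expression(inputs / "expression.tsv")
sens = read_sensitivity(inputs / "sensitivity.tsv")
catalog = read_catalog(inputs / "catalog.tsv")

core_genes = {}
for cat in sorted(catalog.categories):
    table_path = int_dir / f"{cat}.tsv"
    if not table_path.exists():
        continue
    table = pd.read_csv(table_path, sep="\t")
    genes = sorted(table.loc[table["retained"], "gene"])
    if len(genes) < 2:
        print(f"{cat}: fewer than 2 retained genes, skipped")
        continue
    # group the category's drugs by identical label vectors; one run per group
    patterns = {}
    for d in catalog.categories[cat]:
        y = tuple(sens.for_drug(d).sort_values("cell_line")["label"])
        patterns.setdefault(y, []).append(d)
    for drugs in patterns.values():
        rep = drugs[0]
        s = stage_seed(RUN_CFG.seed, "select", f"{cat}/{rep}")
        X, y, gl = build_feature_matrix(expr, sens, rep, genes)
        rankings = [
            rf_importance(X, y, gl, n_iters=RUN_CFG.rf_iters,
                          n_trees=RUN_CFG.rf_trees,
                          train_frac=RUN_CFG.train_frac, seed=s),
            ga_select(X, y, gl, pop_size=RUN_CFG.ga_pop_size,
                      n_generations=RUN_CFG.ga_generations, seed=s),
            rfe_rank(X, y, gl, step=RUN_CFG.rfe_step, seed=s),
        ]
        consensus = aggregate_ranks(rankings)
        consensus.to_csv(out / f"{cat}_{rep}.tsv", sep="\t", index=False)
        top = select_core_genes(consensus, min(RUN_CFG.k_core_genes, len(gl)))
        print(f"{cat}/{rep} ({len(drugs)} drugs share this label pattern): "
              f"top-{len(top)} consensus genes {top}")
        core_genes.setdefault(cat, top)

(out / "core_genes.json").write_text(json.dumps(core_genes, indent=1, sort_keys=True))
print(f"core genes written to {out / 'core_genes.json'}")
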