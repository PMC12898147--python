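"""Per-category resistance classifiers on the consensus core genes.

Z-score standardization fitted per training fold, SMOTE inside folds,
grid-searched random forest under stratified 5-fold CV scored by ROC AUC.
Writes one JSON report per category under results/classify/.
"""

import json

from common import RUN_CFG, results_dir
from resistome.classify import cv_grid_search
from resistome.io import read_expression, read_sensitivity
from resistome.pipeline import stage_seed
from resistome.selection import build_feature_matrix

inputs = results_dir("inputs")
sel_dir = results_dir("select")
out = results_dir("classify")

expr = read_expression(inputs / "expression.tsv")
sens = read_sensitivity(inputs / "sensitivity.tsv")
core_genes = json.loads((sel_dir / "core_genes.json").read_text())
truth = json.loads((inputs / "ground_truth.json").read_text())

for cat, genes in sorted(core_genes.items()):
    drug = truth["consensus_drugs"][cat][0]
    X, y, gl = build_feature_matrix(expr, sens, drug, genes)
    report = cv_grid_search(X, y, grid=RUN_CFG.classifier_grid,
                            n_folds=RUN_CFG.cv_folds,
                            seed=stage_seed(RUN_CFG.seed, "classify", f"{cat}/{drug}"),
                            genes=gl)
    (out / f"{cat}_{drug}.json").write_text(
        json.dumps(report.to_jsonable(), indent=1, sort_keys=True))
    c = report.confusion
    print(f"{cat}/{drug}: ROC AUC {report.roc_auc_mean:.3f} ± {report.roc_auc_sd:.3f}, "
          f"PR AUC {report.pr_auc_mean:.3f} ± {report.pr_auc_sd:.3f}, "
          f"confusion TP={c['tp']} FP={c['fp']} TN={c['tn']} FN={c['fn']}")
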