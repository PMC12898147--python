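"""Calibration and parameter-recovery experiments on synthetic data.

These routines bundle the study-condition runs used to validate the
pipeline: type-I error of the DE test on null data, label-permutation nulls
for the classifier, ORA false-positive calibration, and the planted-gene
recovery experiment at the default generator conditions (100 cell lines,
400 genes, 2 categories x 7 drugs, 5 planted core genes per category,
effect_lfc = 2) with reduced selector hyperparameters (50 random-forest
iterations of 500 trees, GA population 30 over 25 generations, RFE step 1).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

from .classify import cv_auc_fixed, cv_grid_search
from .de import deg_gene_set, run_de
from .enrich import run_ora
from .intersect import threshold_intersection
from .network import analyze_category
from .selection import (
    aggregate_ranks, build_feature_matrix, ga_select, rf_importance, rfe_rank,
    select_core_genes,
)
from .synth import generate_dataset, generate_gene_sets, generate_ppi
from .types import GeneSetCollection

RECOVERY_RF_ITERS = 50
RECOVERY_RF_TREES = 500
RECOVERY_GA_POP = 30
RECOVERY_GA_GENERATIONS = 25
RECOVERY_RFE_STEP = 1


def derive_seeds(master: int, n: int) -> list[int]:
    """n reproducible sub-seeds below 2**31 from one master seed."""
    return [int(s) for s in
            np.random.SeedSequence(int(master) & 0x7FFFFFFF).generate_state(n) & 0x7FFFFFFF]


def de_null_calibration(seed: int, n_genes: int = 2000,
                        n_cell_lines: int = 100) -> dict:
    """Type-I behaviour of the NB-Wald test on an effect-free dataset.

    Returns the fraction of raw Wald p-values below 0.05 and the number of
    post-BH significant DEG calls (|lfc| >= 1 and padj < 0.05), which should
    sit near 0.05 and 0 respectively.
    """
    expr, sens, _, _ = generate_dataset(
        n_cell_lines=n_cell_lines, n_genes=n_genes, effect_lfc=0.0, seed=seed)
    table = run_de(expr, sens, sens.drugs[0])
    return {
        "type1_rate": float((table["pvalue"] < 0.05).mean()),
        "n_significant": int(table["significant"].sum()),
        "n_genes": n_genes,
    }


def permutation_null_auc(seed: int, n_permutations: int = 20) -> dict:
    """Classifier AUC under label permutation: should center on 0.5.

    Features are the planted core genes of one category of an effect-2
    dataset; only the labels are shuffled, destroying the association.
    """
    expr, sens, _, truth = generate_dataset(seed=seed)
    cat = "CAT0"
    drug = truth.consensus_drugs[cat][0]
    X, y, _ = build_feature_matrix(expr, sens, drug,
                                   truth.planted_core_genes[cat])
    rng = np.random.default_rng(seed)
    aucs = []
    for i in range(n_permutations):
        y_perm = rng.permutation(y)
        aucs.append(cv_auc_fixed(X, y_perm, seed=int(rng.integers(0, 2**31 - 1)),
                                 n_estimators=100))
    return {"mean_auc": float(np.mean(aucs)), "aucs": aucs,
            "n_permutations": n_permutations}


def ora_null_calibration(seed: int, n_replicates: int = 200, n_sets: int = 20,
                         set_size: int = 40, query_size: int = 40,
                         universe_size: int = 400) -> dict:
    """Fraction of gene sets flagged at p < 0.05 by random queries.

    Also returns the exact discrete expectation of that fraction: the
    hypergeometric test is discrete, so the attainable level is the tail
    probability at the smallest overlap whose p-value drops below 0.05.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(universe_size)]
    sets = {
        f"S{i:03d}": ("random", frozenset(rng.choice(genes, set_size, replace=False)))
        for i in range(n_sets)
    }
    collection = GeneSetCollection(sets=sets, universe=genes)
    flagged = total = 0
    for _ in range(n_replicates):
        query = set(rng.choice(genes, query_size, replace=False))
        res = run_ora(query, collection)
        flagged += int((res["pvalue"] < 0.05).sum())
        total += len(res)
    # exact attainable level for (K, n, N) fixed across sets
    N, K, n = universe_size, set_size, query_size
    tail = hypergeom.sf(np.arange(0, min(K, n) + 1) - 1, N, K, n)
    k_min = int(np.argmax(tail < 0.05))
    exact = float(tail[k_min]) if tail[k_min] < 0.05 else 0.0
    return {"flag_rate": flagged / total, "exact_expectation": exact,
            "n_tests": total}


def recovery_run(seed: int, k_top: int = 5, fitness_trees: int = 15) -> dict:
    """One seed of the planted-structure recovery experiment.

    Generates the default study-condition dataset, runs DE for all drugs,
    checks the 70 % intersection (both categories), then runs consensus
    selection, the classifier, the PPI core-gene route, and ORA. The
    selection + classifier block runs on one category (alternating with
    seed parity); intersection, network, and ORA checks cover both.
    """
    expr, sens, catalog, truth = generate_dataset(seed=seed)
    deg = {d: deg_gene_set(run_de(expr, sens, d)) for d in sens.drugs}
    cats = sorted(catalog.categories)

    intersection_ok = True
    retained_by_cat = {}
    for cat in cats:
        lists = {d: deg[d] for d in catalog.categories[cat]}
        retained, _, _ = threshold_intersection(lists, 0.70)
        retained_by_cat[cat] = retained
        planted = set(truth.planted_core_genes[cat])
        decoys = set(truth.decoy_genes[cat])
        if not planted <= retained or decoys & retained:
            intersection_ok = False

    cat_eval = cats[seed % len(cats)]
    planted_eval = set(truth.planted_core_genes[cat_eval])
    drug = truth.consensus_drugs[cat_eval][0]
    genes = sorted(retained_by_cat[cat_eval])
    X, y, gl = build_feature_matrix(expr, sens, drug, genes)
    rf = rf_importance(X, y, gl, n_iters=RECOVERY_RF_ITERS,
                       n_trees=RECOVERY_RF_TREES, seed=seed)
    ga = ga_select(X, y, gl, pop_size=RECOVERY_GA_POP,
                   n_generations=RECOVERY_GA_GENERATIONS, seed=seed,
                   fitness_trees=fitness_trees)
    rfe = rfe_rank(X, y, gl, step=RECOVERY_RFE_STEP, seed=seed)
    consensus = aggregate_ranks([rf, ga, rfe])
    top = select_core_genes(consensus, min(k_top, len(gl)))
    precision = len(set(top) & planted_eval) / len(top)

    report = cv_grid_search(
        X[:, [gl.index(g) for g in top]], y,
        grid=[{"n_estimators": 200}], n_folds=5, seed=seed)

    edges = generate_ppi(expr.gene_ids, truth.all_planted(), seed=seed)
    hubs_all_core = True
    for cat in cats:
        lists = {d: deg[d] for d in catalog.categories[cat]}
        result = analyze_category(cat, lists, edges, frac=0.60)
        if not set(truth.planted_core_genes[cat]) <= result.core_genes():
            hubs_all_core = False

    gmt = generate_gene_sets(expr.gene_ids, truth.planted_core_genes, seed=seed)
    ora = run_ora(set(top), gmt, universe=set(expr.gene_ids))
    ora_first = ora.iloc[0]["set_id"] == f"RESISTANCE_{cat_eval}"

    return {
        "seed": seed,
        "intersection_ok": intersection_ok,
        "precision": precision,
        "roc_auc": report.roc_auc_mean,
        "hubs_all_core": hubs_all_core,
        "ora_first": bool(ora_first),
    }


def recovery_experiment(seeds: list[int]) -> dict:
    """Aggregate the recovery experiment over a list of generator seeds."""
    runs = [recovery_run(s) for s in seeds]
    return {
        "runs": runs,
        "n_seeds": len(runs),
        "intersection_ok_count": sum(r["intersection_ok"] for r in runs),
        "mean_precision": float(np.mean([r["precision"] for r in runs])),
        "mean_roc_auc": float(np.mean([r["roc_auc"] for r in runs])),
        "hubs_core_count": sum(r["hubs_all_core"] for r in runs),
        "ora_first_count": sum(r["ora_first"] for r in runs),
    }
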