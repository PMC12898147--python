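"""End-to-end orchestration: simulate → de → intersect → select → classify
→ network → enrich, with deterministic sub-seeding and a run manifest.

One master seed expands into per-stage, per-item sub-seeds through a
counter scheme keyed by stage name and a CRC of the drug/category id, so
adding a drug never perturbs another drug's results. The manifest records
the config snapshot, seeds, and SHA-256 digests of every file written;
re-running with the same config and seed reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, SyntheticConfig
from .classify import cv_grid_search
from .de import deg_gene_set, run_de
from .enrich import run_ora
from .intersect import filter_categories, occurrence_table, pairwise_overlap_means
from .io import (
    read_catalog, read_edge_list, read_expression, read_gmt, read_sensitivity,
    write_catalog, write_edge_list, write_expression, write_gmt, write_sensitivity,
)
from .network import analyze_category, overlap_report
from .selection import (
    aggregate_ranks, build_feature_matrix, ga_select, rf_importance, rfe_rank,
    select_core_genes,
)
from .synth import generate_dataset, generate_gene_sets, generate_ppi
from .types import ExpressionMatrix, ResistomeError

log = logging.getLogger(__name__)


class PipelineError(ResistomeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def stage_seed(master: int, stage: str, item: str = "") -> int:
    """Deterministic sub-seed for (stage, item), independent of run order."""
    key = np.random.SeedSequence(
        [int(master) & 0x7FFFFFFF,
         zlib.crc32(stage.encode()),
         zlib.crc32(item.encode())]
    )
    return int(key.generate_state(1)[0] & 0x7FFFFFFF)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_inputs(syn: SyntheticConfig, out_dir: Path, seed: int) -> dict:
    """Write the five synthetic input files plus the ground-truth JSON."""
    out_dir.mkdir(parents=True, exist_ok=True)
    expr, sens, catalog, truth = generate_dataset(
        n_cell_lines=syn.n_cell_lines, n_genes=syn.n_genes, n_drugs=syn.n_drugs,
        n_categories=syn.n_categories, n_core_per_category=syn.n_core_per_category,
        effect_lfc=syn.effect_lfc, dispersion=syn.dispersion,
        resistant_fraction=syn.resistant_fraction, mode=syn.mode,
        seed=stage_seed(seed, "simulate"),
    )
    if isinstance(expr, dict):
        raise PipelineError("simulate", "per_drug mode is not file-backed in the pipeline")
    hubs = truth.all_planted()
    edges = generate_ppi(expr.gene_ids, hubs, seed=stage_seed(seed, "ppi"))
    sets = generate_gene_sets(expr.gene_ids, truth.planted_core_genes,
                              seed=stage_seed(seed, "gene_sets"))
    write_expression(expr, out_dir / "expression.tsv")
    write_sensitivity(sens, out_dir / "sensitivity.tsv")
    write_catalog(catalog, out_dir / "catalog.tsv")
    write_edge_list(edges, out_dir / "ppi.tsv")
    write_gmt(sets, out_dir / "gene_sets.gmt")
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truth.to_jsonable(), indent=1, sort_keys=True))
    return {"n_drugs": syn.n_drugs, "n_genes": expr.n_genes}


def _dedupe_by_labels(expr: ExpressionMatrix, sens, drugs: list[str]):
    """Group a category's drugs by identical label vectors.

    Drugs keyed to the same resistant cell-line partition have identical
    feature matrices and labels, hence identical downstream results; the
    computation runs once per group and is attributed to every member.
    """
    groups: dict[bytes, list[str]] = {}
    for d in drugs:
        recs = sens.for_drug(d)
        present = tuple(c for c in expr.cell_line_ids if c in set(recs["cell_line"]))
        y = sens.labels_for(d, list(present))
        groups.setdefault((present, y.tobytes()), []).append(d)
    return [v for v in groups.values()]


def run_pipeline(run_cfg: RunConfig, out_dir: str | Path,
                 syn_cfg: SyntheticConfig | None = None,
                 inputs_dir: str | Path | None = None) -> dict:
    """Execute every stage and return the manifest (also written to disk).

    Either ``syn_cfg`` (simulate the inputs) or ``inputs_dir`` (load
    pre-existing input files) must be provided.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = run_cfg.seed
    started = time.time()

    if inputs_dir is None:
        if syn_cfg is None:
            raise PipelineError("config", "need synthetic config or an inputs directory")
        inputs = out / "inputs"
        simulate_inputs(syn_cfg, inputs, seed)
    else:
        inputs = Path(inputs_dir)
        for name in ("expression.tsv", "sensitivity.tsv", "catalog.tsv", "ppi.tsv"):
            if not (inputs / name).exists():
                raise PipelineError("inputs", f"missing input file {name!r}")

    try:
        expr = read_expression(inputs / "expression.tsv")
        sens = read_sensitivity(inputs / "sensitivity.tsv")
        catalog = read_catalog(inputs / "catalog.tsv")
        edges = read_edge_list(inputs / "ppi.tsv")
        gmt = read_gmt(inputs / "gene_sets.gmt") if (inputs / "gene_sets.gmt").exists() else None
    except ResistomeError as e:
        raise PipelineError("inputs", str(e)) from e

    # ---- de ----
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    usable = set(expr.cell_line_ids)
    deg_tables: dict[str, pd.DataFrame] = {}
    for drug in sens.drugs:
        try:
            deg_tables[drug] = run_de(expr, sens, drug, run_cfg)
        except ResistomeError as e:
            raise PipelineError("de", f"drug {drug!r}: {e}") from e
        deg_tables[drug].to_csv(de_dir / f"{drug}.tsv", sep="\t", index=False)
    log.info("de: %d drugs processed", len(deg_tables))

    # ---- intersect ----
    admitted = filter_categories(catalog, run_cfg.min_drugs_per_category,
                                 usable_drugs=set(deg_tables))
    if not admitted:
        raise PipelineError("intersect", "no category admitted by the drug-count filter")
    int_dir = out / "intersect"
    int_dir.mkdir(exist_ok=True)
    retained: dict[str, list[str]] = {}
    for cat, drugs in admitted.items():
        lists = {d: deg_gene_set(deg_tables[d]) for d in drugs}
        try:
            table = occurrence_table(lists, run_cfg.intersect_frac)
        except ResistomeError as e:
            raise PipelineError("intersect", f"category {cat!r}: {e}") from e
        table.to_csv(int_dir / f"{cat}.tsv", sep="\t", index=False)
        pairwise_overlap_means(lists).to_csv(
            int_dir / f"{cat}_drug_overlap.tsv", sep="\t", index=False)
        retained[cat] = sorted(table.loc[table["retained"], "gene"])
        log.info("intersect[%s]: %d genes retained of %d observed",
                 cat, len(retained[cat]), len(table))

    # ---- select + classify (per drug; identical-label drugs computed once) ----
    sel_dir = out / "select"
    sel_dir.mkdir(exist_ok=True)
    clf_dir = out / "classify"
    clf_dir.mkdir(exist_ok=True)
    ml_core: dict[str, list[str]] = {}
    for cat, drugs in admitted.items():
        genes = retained[cat]
        if len(genes) < 2:
            raise PipelineError("select",
                                f"category {cat!r}: fewer than 2 retained genes")
        for group in _dedupe_by_labels(expr, sens, drugs):
            rep = group[0]
            s = stage_seed(seed, "select", f"{cat}/{rep}")
            try:
                X, y, gl = build_feature_matrix(expr, sens, rep, genes)
                rf = rf_importance(X, y, gl, n_iters=run_cfg.rf_iters,
                                   n_trees=run_cfg.rf_trees,
                                   train_frac=run_cfg.train_frac, seed=s)
                ga = ga_select(X, y, gl, pop_size=run_cfg.ga_pop_size,
                               n_generations=run_cfg.ga_generations,
                               tournament_k=run_cfg.ga_tournament_k,
                               crossover_rate=run_cfg.ga_crossover_rate,
                               mutation_rate=run_cfg.ga_mutation_rate, seed=s)
                rfe = rfe_rank(X, y, gl, step=run_cfg.rfe_step, seed=s)
                consensus = aggregate_ranks([rf, ga, rfe])
                k = min(run_cfg.k_core_genes, len(gl))
                top = select_core_genes(consensus, k)
                report = cv_grid_search(
                    X[:, [gl.index(g) for g in top]], y,
                    grid=run_cfg.classifier_grid, n_folds=run_cfg.cv_folds,
                    seed=stage_seed(seed, "classify", f"{cat}/{rep}"),
                    use_smote=run_cfg.use_smote, undersample=run_cfg.undersample,
                    smote_k=run_cfg.smote_k_neighbors, genes=top)
            except ResistomeError as e:
                raise PipelineError("select", f"{cat}/{rep}: {e}") from e
            for d in group:
                consensus.to_csv(sel_dir / f"{cat}_{d}.tsv", sep="\t", index=False)
                (clf_dir / f"{cat}_{d}.json").write_text(
                    json.dumps(report.to_jsonable(), indent=1, sort_keys=True))
            ml_core.setdefault(cat, top)
        log.info("select[%s]: %d candidate genes, top-%d carried forward",
                 cat, len(genes), len(ml_core[cat]))

    # ---- network ----
    net_dir = out / "network"
    net_dir.mkdir(exist_ok=True)
    for cat, drugs in admitted.items():
        lists = {d: deg_gene_set(deg_tables[d]) for d in drugs}
        try:
            result = analyze_category(cat, lists, edges, frac=run_cfg.ppi_frac,
                                      min_score=run_cfg.min_ppi_score)
        except ResistomeError as e:
            raise PipelineError("network", f"category {cat!r}: {e}") from e
        result.nodes.to_csv(net_dir / f"{cat}_nodes.tsv", sep="\t", index=False)
        overlap = overlap_report(result.core_genes(), set(ml_core[cat]))
        (net_dir / f"{cat}_overlap.json").write_text(
            json.dumps(overlap, indent=1, sort_keys=True))

    # ---- enrich ----
    if gmt is not None:
        enr_dir = out / "enrich"
        enr_dir.mkdir(exist_ok=True)
        universe = set(expr.gene_ids)
        for cat in admitted:
            try:
                res = run_ora(set(ml_core[cat]), gmt, universe=universe)
            except ResistomeError as e:
                raise PipelineError("enrich", f"category {cat!r}: {e}") from e
            res.to_csv(enr_dir / f"{cat}.tsv", sep="\t", index=False)

    # ---- manifest ----
    digests = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digests[str(path.relative_to(out))] = _sha256(path)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": run_cfg.to_dict(),
        "synthetic": syn_cfg.to_dict() if syn_cfg else None,
        "inputs_dir": str(inputs),
        "digests": digests,
        "started": started,
        "finished": time.time(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
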