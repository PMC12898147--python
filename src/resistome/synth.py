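"""Synthetic DepMap-like inputs with planted ground truth.

The generator emulates the statistical structure the pipeline assumes:
negative-binomial baseline expression over cell lines, per-drug
sensitive/resistant partitions derived from viability log2FC signs, a
multi-label drug catalog, a scale-free-ish PPI edge list, and GMT gene
sets — all seeded and bit-reproducible.

Planted structure per drug category:

* a *consensus* resistant cell-line set used by ``ceil(0.7 * m)`` of the
  category's ``m`` drugs, and an independent *minority* resistant set used
  by the remaining drugs (in the default shared-expression mode a gene's
  "effect under a fraction of drugs" is realized through which drugs key
  their labels to which cell set);
* **core genes** — elevated ``2**effect_lfc``-fold in consensus-resistant
  lines: differentially expressed for >= 70 % of the category's drugs and
  planted as hubs of the PPI graph;
* **decoy genes** — elevated only in minority-resistant lines: DE for
  < 70 % of drugs, so the thresholded intersection must exclude them;
* **module genes** — elevated in consensus-resistant lines with a weaker
  effect (0.9 x) and much higher dispersion: they pass the DE thresholds
  and populate the category's PPI subnetwork as non-hub neighbors, but are
  individually poorer classifiers than core genes.

A ``per_drug`` mode instead draws an independent count matrix per drug with
the effect applied literally to that drug's resistant lines.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .intersect import required_count
from .types import (
    DrugCatalog,
    ExpressionMatrix,
    GeneSetCollection,
    GroundTruth,
    ResistomeError,
    SensitivityTable,
)

import pandas as pd

log = logging.getLogger(__name__)

MODULE_EFFECT_SCALE = 0.9
MODULE_DISPERSION = 1.5


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             alpha: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion alpha) with variance mean + alpha * mean^2."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    size = 1.0 / np.maximum(alpha, 1e-8)
    p = size / (size + mean)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = alpha < 1e-6  # effectively Poisson; avoid huge NB size params
    out[tiny] = rng.poisson(mean[tiny])
    out[~tiny] = rng.negative_binomial(size[~tiny], p[~tiny])
    return out


def generate_dataset(n_cell_lines: int = 100, n_genes: int = 400,
                     n_drugs: int = 14, n_categories: int = 2,
                     n_core_per_category: int = 5, effect_lfc: float = 2.0,
                     dispersion: float = 0.4, seed: int = 0,
                     resistant_fraction: float = 0.5, mode: str = "shared",
                     consensus_frac: float = 0.70,
                     module_effect_lfc: float | None = None,
                     module_dispersion: float = MODULE_DISPERSION,
                     ) -> tuple[ExpressionMatrix | dict, SensitivityTable, DrugCatalog, GroundTruth]:
    """Generate a full synthetic input bundle with known planted structure.

    Returns ``(expression, sensitivity, catalog, truth)``; in ``per_drug``
    mode the first element is a dict of per-drug :class:`ExpressionMatrix`.
    With ``effect_lfc = 0`` every planted effect vanishes and the dataset
    is an exact null.
    """
    if n_cell_lines < 8:
        raise ResistomeError("need at least 8 cell lines")
    if n_categories < 1 or n_drugs < 2 * n_categories:
        raise ResistomeError("need at least 2 drugs per category")
    if dispersion <= 0 or module_dispersion <= 0:
        raise ResistomeError("dispersions must be positive")
    if not (0.0 < resistant_fraction < 1.0):
        raise ResistomeError("resistant_fraction must be in (0, 1)")
    if mode not in ("shared", "per_drug"):
        raise ResistomeError(f"unknown mode {mode!r}")
    if module_effect_lfc is None:
        module_effect_lfc = MODULE_EFFECT_SCALE * effect_lfc

    n_hubs = n_categories * n_core_per_category
    n_module_per_cat = n_hubs  # one module neighbor per hub per category
    n_decoy_per_cat = n_core_per_category
    n_special = n_hubs + n_categories * (n_module_per_cat + n_decoy_per_cat)
    if n_genes < n_special + 10:
        raise ResistomeError(
            f"n_genes={n_genes} too small for {n_special} planted genes plus background"
        )

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(n_genes)]
    cell_ids = [f"CL{i:04d}" for i in range(n_cell_lines)]

    # gene layout: [cores by category][modules by category][decoys by category][nulls]
    pos = 0
    core: dict[str, list[str]] = {}
    cats = [f"CAT{c}" for c in range(n_categories)]
    for c in cats:
        core[c] = gene_ids[pos:pos + n_core_per_category]
        pos += n_core_per_category
    module: dict[str, list[str]] = {}
    for c in cats:
        module[c] = gene_ids[pos:pos + n_module_per_cat]
        pos += n_module_per_cat
    decoy: dict[str, list[str]] = {}
    for c in cats:
        decoy[c] = gene_ids[pos:pos + n_decoy_per_cat]
        pos += n_decoy_per_cat

    # drugs round-robin over categories; consensus block = ceil(0.7 m)
    drug_ids = [f"DRUG{j:03d}" for j in range(n_drugs)]
    drugs_by_cat = {c: [] for c in cats}
    for j, d in enumerate(drug_ids):
        drugs_by_cat[cats[j % n_categories]].append(d)
    consensus_drugs, minority_drugs = {}, {}
    for c in cats:
        m = len(drugs_by_cat[c])
        k_aff = required_count(m, consensus_frac)
        consensus_drugs[c] = drugs_by_cat[c][:k_aff]
        minority_drugs[c] = drugs_by_cat[c][k_aff:]
        if not minority_drugs[c]:
            log.info("generate_dataset: category %s has no minority drugs; "
                     "its decoys carry no effect", c)
    catalog = DrugCatalog(entries={d: {c} for c in cats for d in drugs_by_cat[c]})

    # resistant cell-line partitions
    n_res = int(round(resistant_fraction * n_cell_lines))
    if not (0 < n_res < n_cell_lines):
        raise ResistomeError(
            "resistant_fraction leaves a drug single-class; adjust parameters"
        )
    consensus_cells = {c: sorted(rng.choice(cell_ids, size=n_res, replace=False))
                       for c in cats}
    minority_cells = {c: sorted(rng.choice(cell_ids, size=n_res, replace=False))
                      for c in cats}
    resistant_cells = {}
    for c in cats:
        for d in consensus_drugs[c]:
            resistant_cells[d] = consensus_cells[c]
        for d in minority_drugs[c]:
            resistant_cells[d] = minority_cells[c]

    # sensitivity log2FCs: sign carries the label, magnitude is nuisance
    rows = []
    for d in drug_ids:
        res = set(resistant_cells[d])
        mag = rng.uniform(0.05, 2.0, size=n_cell_lines)
        for i, cl in enumerate(cell_ids):
            rows.append((cl, d, mag[i] if cl in res else -mag[i]))
    sens = SensitivityTable(records=pd.DataFrame(rows, columns=["cell_line", "drug", "log2fc"]))

    # per-gene baselines and dispersions
    base = np.exp(rng.normal(4.0, 1.0, size=n_genes))  # median ~55 counts
    alpha = np.full(n_genes, float(dispersion))
    gidx = {g: j for j, g in enumerate(gene_ids)}
    for c in cats:
        for g in module[c]:
            alpha[gidx[g]] = module_dispersion
    lib = np.exp(rng.normal(0.0, 0.15, size=n_cell_lines))  # library-size variation

    cell_pos = {cl: i for i, cl in enumerate(cell_ids)}

    def elevation_shared() -> np.ndarray:
        """log2 elevation matrix (cells x genes) in shared mode."""
        lfc = np.zeros((n_cell_lines, n_genes))
        for c in cats:
            cons = [cell_pos[x] for x in consensus_cells[c]]
            mino = [cell_pos[x] for x in minority_cells[c]]
            for g in core[c]:
                lfc[cons, gidx[g]] = effect_lfc
            for g in module[c]:
                lfc[cons, gidx[g]] = module_effect_lfc
            for g in decoy[c]:
                lfc[mino, gidx[g]] = effect_lfc
        return lfc

    def draw(lfc: np.ndarray) -> ExpressionMatrix:
        mean = base[None, :] * lib[:, None] * np.exp2(lfc)
        counts = _nb_draw(rng, mean, alpha[None, :])
        return ExpressionMatrix(cell_line_ids=list(cell_ids),
                                gene_ids=list(gene_ids), counts=counts)

    if mode == "shared":
        expr: ExpressionMatrix | dict = draw(elevation_shared())
    else:
        expr = {}
        for c in cats:
            for d in drugs_by_cat[c]:
                lfc = np.zeros((n_cell_lines, n_genes))
                res = [cell_pos[x] for x in resistant_cells[d]]
                if d in consensus_drugs[c]:
                    for g in core[c]:
                        lfc[res, gidx[g]] = effect_lfc
                    for g in module[c]:
                        lfc[res, gidx[g]] = module_effect_lfc
                else:
                    for g in decoy[c]:
                        lfc[res, gidx[g]] = effect_lfc
                expr[d] = draw(lfc)

    truth = GroundTruth(
        planted_core_genes={c: list(core[c]) for c in cats},
        decoy_genes={c: list(decoy[c]) for c in cats},
        module_genes={c: list(module[c]) for c in cats},
        consensus_drugs=consensus_drugs,
        minority_drugs=minority_drugs,
        effect_lfc=float(effect_lfc),
        module_effect_lfc=float(module_effect_lfc),
        baseline_means=dict(zip(gene_ids, base.tolist())),
        dispersion=dict(zip(gene_ids, alpha.tolist())),
        resistant_fraction={d: n_res / n_cell_lines for d in drug_ids},
        resistant_cells={d: list(v) for d, v in resistant_cells.items()},
    )
    return expr, sens, catalog, truth


def generate_ppi(gene_ids: list[str], planted_hubs: set, seed: int = 0,
                 extra_edge_prob: float = 0.4) -> list[tuple[str, str, float]]:
    """Scale-free-ish PPI edge list with the planted hubs as centers.

    Construction: hubs are chained together; every other gene attaches to a
    hub in deterministic round-robin order (guaranteeing each hub a large,
    balanced neighborhood and hence betweenness far above the median), and
    with probability ``extra_edge_prob`` adds one preferential-attachment
    edge to an already-placed node once at least 4 nodes exist. Structural
    (hub) edges carry confidence scores in [0.6, 1]; extras in [0.2, 1].
    """
    gene_ids = list(gene_ids)
    if len(gene_ids) < 3:
        raise ResistomeError("PPI generation needs at least 3 genes")
    hubs = [g for g in gene_ids if g in set(planted_hubs)]
    if not hubs:
        raise ResistomeError("at least one planted hub required")
    if set(planted_hubs) - set(gene_ids):
        raise ResistomeError("planted hubs must be a subset of gene_ids")

    rng = np.random.default_rng(seed)
    edges: dict[tuple[str, str], float] = {}
    degree: dict[str, int] = {h: 0 for h in hubs}
    placed: list[str] = list(hubs)

    def add_edge(u: str, v: str, lo: float, hi: float) -> None:
        if u == v:
            return
        key = (u, v) if u < v else (v, u)
        if key in edges:
            return
        edges[key] = float(rng.uniform(lo, hi))
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1

    for a, b in zip(hubs, hubs[1:]):
        add_edge(a, b, 0.6, 1.0)

    non_hubs = [g for g in gene_ids if g not in set(hubs)]
    for j, g in enumerate(non_hubs):
        target_hub = hubs[j % len(hubs)]
        degree.setdefault(g, 0)
        add_edge(g, target_hub, 0.6, 1.0)
        if len(placed) >= 4 and rng.random() < extra_edge_prob:
            weights = np.array([degree[v] for v in placed], dtype=float)
            weights = np.maximum(weights, 1e-9)
            partner = placed[rng.choice(len(placed), p=weights / weights.sum())]
            add_edge(g, partner, 0.2, 1.0)
        placed.append(g)

    return [(u, v, s) for (u, v), s in sorted(edges.items())]


def generate_gene_sets(gene_ids: list[str], planted_core_genes,
                       n_sets: int = 20, seed: int = 0, set_size: int = 25,
                       target_frac: float = 0.8) -> GeneSetCollection:
    """GMT-style collection with one planted "resistance" set per category.

    ``planted_core_genes`` may be a flat gene set (one target set) or a
    mapping category -> genes (one target set per category). Each target
    set contains at least ``target_frac`` of its planted genes plus random
    filler up to ``set_size``; the remaining sets are uniform random draws.
    The collection's universe is ``gene_ids``.
    """
    if n_sets < 2:
        raise ResistomeError("need at least 2 gene sets")
    gene_ids = list(gene_ids)
    if isinstance(planted_core_genes, dict):
        targets = {f"RESISTANCE_{c}": sorted(gs) for c, gs in planted_core_genes.items()}
    else:
        targets = {"RESISTANCE": sorted(planted_core_genes)}
    if len(targets) >= n_sets:
        raise ResistomeError("n_sets must exceed the number of planted categories")
    for name, genes in targets.items():
        if set(genes) - set(gene_ids):
            raise ResistomeError(f"planted genes of {name} not all in gene_ids")

    rng = np.random.default_rng(seed)
    sets: dict[str, tuple] = {}
    for name, planted in targets.items():
        n_take = math.ceil(target_frac * len(planted))
        members = set(rng.choice(planted, size=n_take, replace=False))
        filler_pool = [g for g in gene_ids if g not in set(planted)]
        n_fill = max(0, set_size - len(members))
        members |= set(rng.choice(filler_pool, size=n_fill, replace=False))
        sets[name] = ("planted resistance programme", frozenset(members))
    for i in range(n_sets - len(targets)):
        members = rng.choice(gene_ids, size=set_size, replace=False)
        sets[f"RANDOM{i:03d}"] = ("random background set", frozenset(members))
    return GeneSetCollection(sets=sets, universe=gene_ids)
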