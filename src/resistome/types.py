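"""Domain types shared by every pipeline stage.

The pipeline manipulates four kinds of input data: a cell-line × gene count
matrix of baseline expression, a long table of per-(cell line, drug)
drug-sensitivity log2 fold changes, a multi-label drug → pharmacological
category catalog, and gene-set collections for over-representation analysis.
Each type validates its own invariants on construction so downstream stages
can assume well-formed data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SENSITIVE = "sensitive"
RESISTANT = "resistant"


class ResistomeError(ValueError):
    """Base class for validation and contract errors raised by this package."""


def classify_sensitivity(log2fc: float) -> str:
    """Label a (cell line, drug) pair from its viability log2 fold change.

    A negative log2FC means the compound reduced viability, i.e. the cell
    line is *sensitive*; zero or positive means *resistant*. The boundary
    value 0.0 is resistant.

    Parameters
    ----------
    log2fc : float
        Finite log2 fold change of cell viability under treatment.

    Returns
    -------
    str
        ``"sensitive"`` iff ``log2fc < 0``, else ``"resistant"``.
    """
    if not math.isfinite(log2fc):
        raise ResistomeError(f"non-finite log2FC value: {log2fc!r}")
    return SENSITIVE if log2fc < 0 else RESISTANT


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ResistomeError(f"duplicate {what} id(s): {sorted(set(dups))}")
    return ids


@dataclass
class ExpressionMatrix:
    """Integer count matrix, cell lines (rows) × genes (columns)."""

    cell_line_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.cell_line_ids = _check_unique(self.cell_line_ids, "cell line")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.cell_line_ids), len(self.gene_ids)):
            raise ResistomeError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.cell_line_ids)} cell lines x {len(self.gene_ids)} genes"
            )
        if len(self.cell_line_ids) < 2 or len(self.gene_ids) < 2:
            raise ResistomeError("expression matrix needs at least 2 cell lines and 2 genes")
        if not np.issubdtype(counts.dtype, np.number):
            raise ResistomeError("counts must be numeric")
        if np.any(~np.isfinite(counts.astype(float))):
            raise ResistomeError("counts contain non-finite values")
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise ResistomeError(
                f"negative count at cell line {self.cell_line_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}"
            )
        if np.any(counts != np.floor(counts)):
            raise ResistomeError("counts must be integers")
        self.counts = counts.astype(np.int64)

    @property
    def n_cell_lines(self) -> int:
        return len(self.cell_line_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cell_line_ids, columns=self.gene_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        pos = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise ResistomeError(f"gene id(s) not in matrix: {missing}")
        return np.array([pos[g] for g in genes], dtype=int)

    def cell_index(self, cells: Iterable[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.cell_line_ids)}
        missing = [c for c in cells if c not in pos]
        if missing:
            raise ResistomeError(f"cell line id(s) not in matrix: {missing}")
        return np.array([pos[c] for c in cells], dtype=int)


@dataclass
class SensitivityTable:
    """Long table of (cell line, drug, log2FC) drug-sensitivity records.

    The sensitive/resistant label is always derived from the log2FC sign rule
    (see :func:`classify_sensitivity`), never stored independently.
    """

    records: pd.DataFrame  # columns: cell_line, drug, log2fc

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        required = {"cell_line", "drug", "log2fc"}
        if missing := required - set(df.columns):
            raise ResistomeError(f"sensitivity table missing column(s): {sorted(missing)}")
        df = df[["cell_line", "drug", "log2fc"]].copy()
        df["log2fc"] = df["log2fc"].astype(float)
        bad = df[~np.isfinite(df["log2fc"])]
        if len(bad):
            r = bad.iloc[0]
            raise ResistomeError(
                f"non-finite log2FC for cell line {r.cell_line!r}, drug {r.drug!r}"
            )
        dup = df.duplicated(subset=["cell_line", "drug"])
        if dup.any():
            r = df[dup].iloc[0]
            raise ResistomeError(
                f"duplicate (cell line, drug) pair: ({r.cell_line!r}, {r.drug!r})"
            )
        df["label"] = np.where(df["log2fc"] < 0, SENSITIVE, RESISTANT)
        self.records = df.reset_index(drop=True)

    @property
    def drugs(self) -> list[str]:
        return list(pd.unique(self.records["drug"]))

    def for_drug(self, drug: str) -> pd.DataFrame:
        sub = self.records[self.records["drug"] == drug]
        if sub.empty:
            raise ResistomeError(f"no sensitivity records for drug {drug!r}")
        return sub.reset_index(drop=True)

    def labels_for(self, drug: str, cell_line_ids: list[str]) -> np.ndarray:
        """Binary labels (1 = resistant) for the given cell lines, paired to a drug.

        Cell lines without a record for the drug are reported as an error by
        name; callers drop unmeasured lines before this point.
        """
        sub = self.for_drug(drug).set_index("cell_line")
        missing = [c for c in cell_line_ids if c not in sub.index]
        if missing:
            raise ResistomeError(f"no {drug!r} sensitivity for cell line(s): {missing[:5]}")
        return (sub.loc[cell_line_ids, "label"] == RESISTANT).to_numpy().astype(int)


@dataclass
class DrugCatalog:
    """Multi-label mapping drug id → set of pharmacological category names."""

    entries: Mapping[str, set]

    def __post_init__(self) -> None:
        clean: dict[str, set] = {}
        for drug, cats in dict(self.entries).items():
            cats = {str(c) for c in cats}
            if any(not c for c in cats):
                raise ResistomeError(f"empty category name for drug {drug!r}")
            clean[str(drug)] = cats
        self.entries = clean

    @property
    def categories(self) -> dict[str, list[str]]:
        """Category → sorted drug list (a drug may appear in several)."""
        out: dict[str, list[str]] = {}
        for drug, cats in self.entries.items():
            for c in cats:
                out.setdefault(c, []).append(drug)
        return {c: sorted(ds) for c, ds in sorted(out.items())}

    def drugs_in(self, category: str) -> list[str]:
        return self.categories.get(category, [])


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with an optional explicit universe."""

    sets: Mapping[str, tuple]  # set_id -> (description, frozenset of gene ids)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        clean = {}
        for sid, (desc, members) in dict(self.sets).items():
            members = frozenset(str(g) for g in members)
            if not members:
                raise ResistomeError(f"gene set {sid!r} is empty")
            clean[str(sid)] = (str(desc), members)
        self.sets = clean
        if self.universe is not None:
            self.universe = _check_unique([str(g) for g in self.universe], "universe gene")

    def members(self, set_id: str) -> frozenset:
        return self.sets[set_id][1]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset, for parameter-recovery tests."""

    planted_core_genes: dict[str, list[str]]  # category -> core (hub) genes
    decoy_genes: dict[str, list[str]]         # category -> sub-threshold decoys
    module_genes: dict[str, list[str]]        # category -> weaker shared-signature genes
    consensus_drugs: dict[str, list[str]]     # category -> drugs carrying the shared effect
    minority_drugs: dict[str, list[str]]      # category -> drugs carrying only the decoy effect
    effect_lfc: float
    module_effect_lfc: float
    baseline_means: dict[str, float]
    dispersion: dict[str, float]
    resistant_fraction: dict[str, float]      # per drug
    resistant_cells: dict[str, list[str]]     # per drug

    def __post_init__(self) -> None:
        if not math.isfinite(self.effect_lfc) or not math.isfinite(self.module_effect_lfc):
            raise ResistomeError("effect sizes must be finite")
        if any(a <= 0 for a in self.dispersion.values()):
            raise ResistomeError("dispersions must be positive")

    def all_planted(self) -> set:
        return {g for gs in self.planted_core_genes.values() for g in gs}

    def to_jsonable(self) -> dict:
        return {
            "planted_core_genes": self.planted_core_genes,
            "decoy_genes": self.decoy_genes,
            "module_genes": self.module_genes,
            "consensus_drugs": self.consensus_drugs,
            "minority_drugs": self.minority_drugs,
            "effect_lfc": self.effect_lfc,
            "module_effect_lfc": self.module_effect_lfc,
            "resistant_fraction": self.resistant_fraction,
            "resistant_cells": self.resistant_cells,
        }
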