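"""Readers and writers for the pipeline's delimited-text formats.

TSV is the canonical dialect; comma-separated input is accepted by sniffing
the header line. All writers emit TSV. Gene and cell-line identifiers are
opaque strings — no symbol/accession translation is attempted.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    DrugCatalog,
    ExpressionMatrix,
    GeneSetCollection,
    ResistomeError,
    SensitivityTable,
)

log = logging.getLogger(__name__)


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


def read_expression(path: str | Path, id_map: str | Path | None = None) -> ExpressionMatrix:
    """Read a cell-line × gene count matrix.

    First column holds cell-line ids, header row holds gene ids. An optional
    two-column ``id_map`` file (old id → harmonized id) is applied to the
    cell-line axis; rows whose id is absent from the map are dropped with a
    logged count.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup = sorted({g for g in header if header.count(g) > 1})
    if dup:  # checked on the raw header: pandas silently renames duplicates
        raise ResistomeError(f"{path.name}: duplicate gene column(s): {dup}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise ResistomeError(f"{path.name}: duplicate cell line id(s): {sorted(set(dup))}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ResistomeError(
                f"{path.name}: non-numeric count for gene {col!r}"
                f" (e.g. cell line {bad.index[0]!r}: {bad.iloc[0]!r})"
            )
    if df.isna().any().any():
        raise ResistomeError(f"{path.name}: missing values in count matrix (ragged rows?)")
    if id_map is not None:
        mapping = read_id_map(id_map)
        keep = df.index.isin(mapping)
        n_drop = int((~keep).sum())
        if n_drop:
            log.info("read_expression: dropped %d unmapped cell line(s)", n_drop)
        df = df.loc[keep]
        df.index = [mapping[c] for c in df.index]
    return ExpressionMatrix(
        cell_line_ids=[str(i) for i in df.index],
        gene_ids=[str(c) for c in df.columns],
        counts=df.to_numpy(),
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="cell_line")


def read_id_map(path: str | Path) -> dict[str, str]:
    """Two-column (old id, harmonized id) conversion table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), header=None, dtype=str)
    if df.shape[1] < 2:
        raise ResistomeError(f"{path.name}: id map needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_sensitivity(path: str | Path, id_map: str | Path | None = None) -> SensitivityTable:
    """Read the (cell line, drug, log2FC) long table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    rename = {c: c.strip().lower() for c in df.columns}
    df = df.rename(columns=rename)
    if "log2fc" not in df.columns and "log2_fc" in df.columns:
        df = df.rename(columns={"log2_fc": "log2fc"})
    if id_map is not None:
        mapping = read_id_map(id_map)
        keep = df["cell_line"].isin(mapping)
        n_drop = int((~keep).sum())
        if n_drop:
            log.info("read_sensitivity: dropped %d unmapped record(s)", n_drop)
        df = df.loc[keep].copy()
        df["cell_line"] = df["cell_line"].map(mapping)
    return SensitivityTable(records=df)


def write_sensitivity(table: SensitivityTable, path: str | Path) -> None:
    table.records[["cell_line", "drug", "log2fc"]].to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> DrugCatalog:
    """Read a drug → category table; multi-label cells are '|'-separated."""
    path = Path(path)
    sep = _sniff_sep(path)
    entries: dict[str, set] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader)
        if len(header) < 2:
            raise ResistomeError(f"{path.name}: catalog needs (drug, categories) columns")
        for row in reader:
            if not row or not row[0]:
                continue
            drug = row[0].strip()
            cats = {c.strip() for c in row[1].split("|") if c.strip()}
            if not cats:
                raise ResistomeError(f"{path.name}: drug {drug!r} has no categories")
            entries.setdefault(drug, set()).update(cats)
    return DrugCatalog(entries=entries)


def write_catalog(catalog: DrugCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("drug\tcategories\n")
        for drug in sorted(catalog.entries):
            fh.write(f"{drug}\t{'|'.join(sorted(catalog.entries[drug]))}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line — name, description, then members."""
    path = Path(path)
    sets: dict[str, tuple] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ResistomeError(f"{path.name}:{ln}: GMT line needs name, description, members")
            name, desc, members = parts[0], parts[1], [p for p in parts[2:] if p]
            if name in sets:
                raise ResistomeError(f"{path.name}:{ln}: duplicate gene set {name!r}")
            sets[name] = (desc, frozenset(members))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, (desc, members) in collection.sets.items():
            fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a STRING-export-like 3-column edge list (node, node, score in [0,1]).

    Duplicate undirected edges collapse to the maximum score; self-loops are
    dropped with a logged warning.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    best: dict[tuple[str, str], float] = {}
    n_self = 0
    with open(path) as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader, None)
        if header is None:
            raise ResistomeError(f"{path.name}: empty edge list")
        # tolerate headerless files whose first row already looks like an edge
        rows = []
        try:
            float(header[2])
            rows.append(header)
        except (ValueError, IndexError):
            pass
        rows.extend(reader)
    for ln, row in enumerate(rows, 1):
        if not row:
            continue
        if len(row) < 3:
            raise ResistomeError(f"{path.name}:{ln}: edge row needs (node, node, score)")
        u, v, s = row[0].strip(), row[1].strip(), float(row[2])
        if not (0.0 <= s <= 1.0):
            raise ResistomeError(f"{path.name}:{ln}: score {s} outside [0, 1]")
        if u == v:
            n_self += 1
            continue
        key = (u, v) if u < v else (v, u)
        best[key] = max(best.get(key, 0.0), s)
    if n_self:
        log.warning("read_edge_list: dropped %d self-loop edge(s)", n_self)
    return [(u, v, s) for (u, v), s in sorted(best.items())]


def write_edge_list(edges: list[tuple[str, str, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v, s in edges:
            fh.write(f"{u}\t{v}\t{s:.6g}\n")
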