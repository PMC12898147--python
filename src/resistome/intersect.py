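"""Cross-drug aggregation of per-drug DEG lists within a drug category.

A strict intersection across all drugs of a category is usually close to
empty, because resistance programmes are partly drug-specific. The pipeline
therefore retains genes present in at least a fraction ``frac`` of the
per-drug lists (default 70 %), with the required count computed as
``ceil(frac * n_lists)`` so the "at least" reading holds for every list
count. The same rule at 60 % feeds the PPI stage.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .types import DrugCatalog, ResistomeError

log = logging.getLogger(__name__)


def filter_categories(catalog: DrugCatalog, min_drugs: int = 6,
                      usable_drugs: set | None = None) -> dict[str, list[str]]:
    """Admit categories containing at least ``min_drugs`` usable drugs.

    ``usable_drugs``, when given, restricts counting to drugs with complete
    sensitivity and expression data; a drug in several categories counts
    toward each of them.
    """
    if not catalog.entries:
        raise ResistomeError("empty drug catalog")
    admitted = {}
    for cat, drugs in catalog.categories.items():
        if usable_drugs is not None:
            drugs = [d for d in drugs if d in usable_drugs]
        if len(drugs) >= min_drugs:
            admitted[cat] = drugs
    log.info("filter_categories: admitted %d of %d categories (min_drugs=%d)",
             len(admitted), len(catalog.categories), min_drugs)
    return admitted


def required_count(n_lists: int, frac: float) -> int:
    """Number of lists a gene must occur in: ceil(frac * n_lists)."""
    if not (0.0 < frac <= 1.0):
        raise ResistomeError(f"frac must be in (0, 1], got {frac}")
    return math.ceil(frac * n_lists - 1e-12)  # guard float noise at exact products


def threshold_intersection(deg_lists: Mapping[str, set] | Sequence[set],
                           frac: float = 0.70) -> tuple[set, Counter, int]:
    """Genes present in at least ``ceil(frac * n_lists)`` of the lists.

    Empty lists still count in the denominator — a drug whose DE analysis
    found nothing is evidence of absence. ``frac = 1.0`` reduces to the
    strict intersection.

    Returns (retained gene set, per-gene occurrence counter, required count).
    """
    if isinstance(deg_lists, Mapping):
        lists = list(deg_lists.values())
    else:
        lists = list(deg_lists)
    if not lists:
        raise ResistomeError("no DEG lists to intersect")
    n = len(lists)
    required = required_count(n, frac)
    counts: Counter = Counter()
    for genes in lists:
        counts.update(set(genes))
    n_empty = sum(1 for g in lists if not g)
    if n_empty:
        log.info("threshold_intersection: %d of %d lists empty (still in denominator)",
                 n_empty, n)
    retained = {g for g, c in counts.items() if c >= required}
    return retained, counts, required


def occurrence_table(deg_lists: Mapping[str, set], frac: float = 0.70) -> pd.DataFrame:
    """Tabular view: gene, occurrence count, n_drugs, retained flag."""
    retained, counts, required = threshold_intersection(deg_lists, frac)
    n = len(deg_lists)
    df = pd.DataFrame(
        [(g, c, n, g in retained) for g, c in sorted(counts.items())],
        columns=["gene", "occurrence", "n_drugs", "retained"],
    )
    df.attrs["required"] = required
    return df


def upset_counts(deg_lists: Mapping[str, set]) -> dict[frozenset, int]:
    """Exclusive-intersection sizes over a family of up to 15 gene lists.

    For every non-empty subset S of list names, counts genes belonging to
    exactly the lists in S. Counts sum to the size of the union.
    """
    names = list(deg_lists)
    if len(names) > 15:
        raise ResistomeError(
            f"{len(names)} lists exceed exact-enumeration limit (15); "
            "use pairwise overlaps instead"
        )
    if not names:
        raise ResistomeError("no lists given")
    membership: dict[str, frozenset] = {}
    for name in names:
        for g in deg_lists[name]:
            membership[g] = membership.get(g, frozenset()) | {name}
    out: dict[frozenset, int] = {}
    for sig in membership.values():
        out[sig] = out.get(sig, 0) + 1
    return out


def pairwise_overlap_means(deg_lists: Mapping[str, set]) -> pd.DataFrame:
    """Mean pairwise Jaccard overlap of each drug's list with the others.

    Exported as a candidate notion of a drug's "intersection frequency"
    within its category; no stronger claim is attached to it.
    """
    names = list(deg_lists)
    scores = {n: [] for n in names}
    for a, b in combinations(names, 2):
        sa, sb = set(deg_lists[a]), set(deg_lists[b])
        union = sa | sb
        j = len(sa & sb) / len(union) if union else 0.0
        scores[a].append(j)
        scores[b].append(j)
    rows = [(n, float(pd.Series(v).mean()) if v else 0.0) for n, v in scores.items()]
    return pd.DataFrame(rows, columns=["drug", "mean_pairwise_jaccard"]) \
        .sort_values("mean_pairwise_jaccard", ascending=False, ignore_index=True)
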