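"""Gene-set over-representation analysis (hypergeometric ORA).

Stands in for GO/KEGG enrichment without live database queries: gene sets
are user-supplied GMT collections, keeping results version-independent.
For a query of n genes drawn from a universe of N, a set with K members in
the universe and k members in the query is scored by the exact upper tail
``P(X >= k)``, ``X ~ Hypergeometric(N, K, n)``, with Benjamini-Hochberg
adjustment across the tested sets (shared with the DE stage). Both a
p < 0.05 view and an unfiltered top-N view are reported, since enrichment
summaries are often read under a deliberately relaxed threshold.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust
from .types import GeneSetCollection, ResistomeError

log = logging.getLogger(__name__)


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    Parameters: ``k`` overlap count, ``K`` set size, ``n`` query size,
    ``N`` universe size; requires ``0 <= k <= min(K, n) <= N``.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ResistomeError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def run_ora(query: set, collection: GeneSetCollection,
            universe: set | None = None, top_n: int = 10) -> pd.DataFrame:
    """Over-representation of a query gene list against a set collection.

    The universe defaults to the collection's explicit universe; query genes
    outside the universe are dropped with a logged count, and sets disjoint
    from the universe are skipped rather than tested. Returns a DataFrame
    sorted by p (ties by set id) with columns
    ``set_id, description, k, K, n, N, fold_enrichment, pvalue, padj,
    genes, significant, in_top_n``.
    """
    if universe is None:
        if collection.universe is None:
            raise ResistomeError("no universe: pass one or set it on the collection")
        universe = set(collection.universe)
    universe = set(universe)
    if not universe:
        raise ResistomeError("empty universe")
    query = set(query)
    dropped = query - universe
    if dropped:
        log.info("run_ora: dropped %d query gene(s) outside the universe", len(dropped))
    query &= universe
    if not query:
        raise ResistomeError("empty query after restricting to the universe")

    N, n = len(universe), len(query)
    rows = []
    for sid, (desc, members) in collection.sets.items():
        in_universe = members & universe
        if not in_universe:
            continue
        K = len(in_universe)
        overlap = sorted(query & in_universe)
        k = len(overlap)
        p = hypergeom_test(k, K, n, N)
        fold = (k / n) / (K / N)
        rows.append((sid, desc, k, K, n, N, fold, p, ",".join(overlap)))
    if not rows:
        raise ResistomeError("no gene set intersects the universe")
    df = pd.DataFrame(rows, columns=[
        "set_id", "description", "k", "K", "n", "N",
        "fold_enrichment", "pvalue", "genes",
    ])
    df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    df = df.sort_values(["pvalue", "set_id"], ignore_index=True)
    df["significant"] = df["pvalue"] < 0.05
    df["in_top_n"] = df.index < top_n
    return df
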