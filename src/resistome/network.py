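"""Per-category PPI subnetwork topology and core-gene calling.

Genes appearing in at least 60 % of a category's per-drug DEG lists (same
ceiling rule as the 70 % intersection, shared code path) are mapped onto a
STRING-like protein-interaction edge list. Edges gate on the interaction
confidence score (default 0.4, the conventional "medium confidence" cutoff)
and are treated as unweighted for shortest paths. Core genes are those whose
betweenness centrality lies strictly above the median of the induced
subnetwork; the overlap with the machine-learning consensus genes is the
pipeline's cross-validation of the two routes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .intersect import threshold_intersection
from .types import ResistomeError

log = logging.getLogger(__name__)


def frequency_filter_genes(deg_lists: Mapping[str, set] | Sequence[set],
                           frac: float = 0.60) -> set:
    """Genes present in at least ``ceil(frac * n_drugs)`` DEG lists.

    Identical rule to the 70 % intersection stage, re-exported at the PPI
    stage's 60 % default so both stages share one implementation.
    """
    retained, _, _ = threshold_intersection(deg_lists, frac)
    return retained


def induce_subgraph(edges: Sequence[tuple[str, str, float]], genes: set,
                    min_score: float = 0.4) -> tuple[nx.Graph, set]:
    """Subgraph induced by ``genes`` over a scored edge list.

    Nodes are the selected genes that appear anywhere in the edge list
    (degree-0 nodes are retained when all their edges are filtered out);
    edges survive iff both endpoints are selected and score >= min_score
    (inclusive). Selected genes absent from the edge list entirely are
    returned as the unmapped set — they have no topology and are excluded
    from downstream medians.
    """
    for _, _, s in edges:
        if not (0.0 <= s <= 1.0):
            raise ResistomeError(f"edge score {s} outside [0, 1]")
    known = set()
    for u, v, _ in edges:
        known.add(u)
        known.add(v)
    genes = set(genes)
    mapped = genes & known
    unmapped = genes - known
    if unmapped:
        log.info("induce_subgraph: %d selected gene(s) absent from the edge list",
                 len(unmapped))
    g = nx.Graph()
    g.add_nodes_from(sorted(mapped))
    for u, v, s in edges:
        if u in mapped and v in mapped and s >= min_score:
            g.add_edge(u, v, score=s)
    return g, unmapped


def betweenness(graph: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness on the unweighted graph.

    For each unordered node pair (s, t), every other node v accrues
    ``sigma_st(v) / sigma_st``; pairs in different components contribute
    nothing.
    """
    return {n: float(b) for n, b in
            nx.betweenness_centrality(graph, normalized=False).items()}


def call_core(betweenness_by_gene: Mapping[str, float]) -> tuple[dict[str, bool], float]:
    """Core flags: strictly above the median betweenness of all nodes.

    The median is over every node in the subnetwork, degree-0 nodes
    included; with an even node count it is the mean of the two middle
    values. An all-tied network therefore has no core genes.
    """
    if not betweenness_by_gene:
        raise ResistomeError("no nodes to call core genes on")
    values = np.array(list(betweenness_by_gene.values()), dtype=float)
    med = float(np.median(values))
    return {g: b > med for g, b in betweenness_by_gene.items()}, med


@dataclass
class NetworkCoreResult:
    """Node-level topology metrics and core calls for one drug category."""

    category: str
    nodes: pd.DataFrame  # gene, degree, betweenness, is_core
    median_betweenness: float
    unmapped: set
    overlap_with_ml: set = None  # set after overlap_report

    def core_genes(self) -> set:
        return set(self.nodes.loc[self.nodes["is_core"], "gene"])


def analyze_category(category: str, deg_lists: Mapping[str, set],
                     edges: Sequence[tuple[str, str, float]],
                     frac: float = 0.60, min_score: float = 0.4) -> NetworkCoreResult:
    """Run the full network route for one category's per-drug DEG lists."""
    selected = frequency_filter_genes(deg_lists, frac)
    graph, unmapped = induce_subgraph(edges, selected, min_score)
    if graph.number_of_nodes() == 0:
        raise ResistomeError(
            f"category {category!r}: no selected gene maps to the PPI network"
        )
    bet = betweenness(graph)
    flags, med = call_core(bet)
    nodes = pd.DataFrame({
        "gene": sorted(graph.nodes),
        "degree": [graph.degree(g) for g in sorted(graph.nodes)],
        "betweenness": [bet[g] for g in sorted(graph.nodes)],
        "is_core": [flags[g] for g in sorted(graph.nodes)],
    })
    return NetworkCoreResult(category=category, nodes=nodes,
                             median_betweenness=med, unmapped=unmapped)


def overlap_report(core_network_genes: set, core_ml_genes: set) -> dict:
    """Intersection and Jaccard index of the two core-gene routes."""
    a, b = set(core_network_genes), set(core_ml_genes)
    inter = a & b
    union = a | b
    return {
        "network_core": sorted(a),
        "ml_core": sorted(b),
        "intersection": sorted(inter),
        "n_network": len(a),
        "n_ml": len(b),
        "n_intersection": len(inter),
        "jaccard": (len(inter) / len(union)) if union else 0.0,
    }
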