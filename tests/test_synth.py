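"""Synthetic-generator contracts: determinism, planted structure, PPI, sets."""

import networkx as nx
import numpy as np
import pytest

from resistome.synth import generate_dataset, generate_gene_sets, generate_ppi
from resistome.types import ResistomeError


class TestGenerateDataset:
    def test_same_seed_bit_identical(self):
        a = generate_dataset(n_cell_lines=20, n_genes=80, seed=5)
        b = generate_dataset(n_cell_lines=20, n_genes=80, seed=5)
        assert np.array_equal(a[0].counts, b[0].counts)
        assert a[1].records.equals(b[1].records)
        assert a[3].to_jsonable() == b[3].to_jsonable()

    def test_different_seed_differs(self):
        a = generate_dataset(n_cell_lines=20, n_genes=80, seed=5)
        b = generate_dataset(n_cell_lines=20, n_genes=80, seed=6)
        assert not np.array_equal(a[0].counts, b[0].counts)

    def test_planted_mean_ratio_matches_effect(self):
        """Monte-Carlo check of the NB draw: 2^2 = 4x mean ratio for
        planted genes between consensus-resistant and other cell lines."""
        expr, sens, _, truth = generate_dataset(
            n_cell_lines=100, n_genes=120, effect_lfc=2.0, dispersion=0.05,
            resistant_fraction=0.5, seed=3,
        )
        cat = "CAT0"
        drug = truth.consensus_drugs[cat][0]
        res = set(truth.resistant_cells[drug])
        ridx = [i for i, c in enumerate(expr.cell_line_ids) if c in res]
        sidx = [i for i, c in enumerate(expr.cell_line_ids) if c not in res]
        ratios = []
        for g in truth.planted_core_genes[cat]:
            j = expr.gene_ids.index(g)
            ratios.append(expr.counts[ridx, j].mean() / expr.counts[sidx, j].mean())
        assert all(3.4 <= r <= 4.7 for r in ratios)

    def test_null_dataset_has_no_group_difference(self):
        expr, _, _, truth = generate_dataset(
            n_cell_lines=100, n_genes=120, effect_lfc=0.0, dispersion=0.05, seed=4)
        assert truth.effect_lfc == 0.0 and truth.module_effect_lfc == 0.0
        drug = truth.consensus_drugs["CAT0"][0]
        res = set(truth.resistant_cells[drug])
        ridx = [i for i, c in enumerate(expr.cell_line_ids) if c in res]
        sidx = [i for i, c in enumerate(expr.cell_line_ids) if c not in res]
        for g in truth.planted_core_genes["CAT0"]:
            j = expr.gene_ids.index(g)
            ratio = expr.counts[ridx, j].mean() / expr.counts[sidx, j].mean()
            assert 0.8 <= ratio <= 1.25

    def test_single_class_configuration_rejected(self):
        with pytest.raises(ResistomeError, match="single-class|resistant_fraction"):
            generate_dataset(n_cell_lines=10, n_genes=80,
                             resistant_fraction=0.01, seed=0)

    def test_consensus_block_respects_seventy_percent(self):
        _, _, catalog, truth = generate_dataset(n_cell_lines=20, n_genes=80, seed=7)
        for cat, drugs in catalog.categories.items():
            n_cons = len(truth.consensus_drugs[cat])
            assert n_cons / len(drugs) >= 0.70
            assert len(truth.minority_drugs[cat]) / len(drugs) < 0.70

    def test_every_drug_has_both_labels(self):
        _, sens, _, _ = generate_dataset(n_cell_lines=20, n_genes=80, seed=8)
        for d in sens.drugs:
            labels = set(sens.for_drug(d)["label"])
            assert labels == {"sensitive", "resistant"}

    def test_per_drug_mode_returns_matrix_per_drug(self):
        expr, sens, _, truth = generate_dataset(
            n_cell_lines=20, n_genes=80, mode="per_drug", seed=9)
        assert set(expr) == set(sens.drugs)
        m = expr[sens.drugs[0]]
        assert m.counts.shape == (20, 80)


class TestGeneratePpi:
    def test_three_nodes_star_around_hub(self):
        edges = generate_ppi(["a", "h", "b"], {"h"}, seed=0)
        g = nx.Graph((u, v) for u, v, _ in edges)
        bet = nx.betweenness_centrality(g, normalized=False)
        assert bet["h"] > max(bet["a"], bet["b"])

    def test_same_seed_identical_edges(self):
        genes = [f"g{i}" for i in range(50)]
        hubs = {"g0", "g1"}
        assert generate_ppi(genes, hubs, seed=3) == generate_ppi(genes, hubs, seed=3)

    def test_hubs_in_top_decile_of_degree(self):
        genes = [f"g{i}" for i in range(200)]
        hubs = {f"g{i}" for i in range(5)}
        edges = generate_ppi(genes, hubs, seed=1)
        g = nx.Graph((u, v) for u, v, _ in edges)
        degrees = sorted((d for _, d in g.degree()), reverse=True)
        cutoff = degrees[len(degrees) // 10]
        assert all(g.degree(h) >= cutoff for h in hubs)

    def test_hubs_exceed_median_betweenness(self):
        genes = [f"g{i}" for i in range(120)]
        hubs = {"g0", "g1", "g2"}
        edges = generate_ppi(genes, hubs, seed=2)
        g = nx.Graph((u, v) for u, v, _ in edges)
        bet = nx.betweenness_centrality(g, normalized=False)
        med = np.median(list(bet.values()))
        assert all(bet[h] > med for h in hubs)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ResistomeError, match="at least 3"):
            generate_ppi(["a", "b"], {"a"}, seed=0)

    def test_scores_within_unit_interval(self):
        edges = generate_ppi([f"g{i}" for i in range(30)], {"g0"}, seed=4)
        assert all(0.0 <= s <= 1.0 for _, _, s in edges)


class TestGenerateGeneSets:
    def test_target_set_contains_planted_majority(self):
        genes = [f"g{i}" for i in range(100)]
        planted = {"g1", "g2", "g3", "g4", "g5"}
        coll = generate_gene_sets(genes, planted, n_sets=10, seed=0)
        target = coll.members("RESISTANCE")
        assert len(target & planted) >= np.ceil(0.8 * len(planted))

    def test_two_planted_one_target(self):
        coll = generate_gene_sets([f"g{i}" for i in range(50)], {"g1", "g2"},
                                  n_sets=5, seed=1, set_size=10)
        assert {"g1", "g2"} <= coll.members("RESISTANCE")

    def test_per_category_targets(self):
        coll = generate_gene_sets([f"g{i}" for i in range(60)],
                                  {"A": ["g0", "g1"], "B": ["g2", "g3"]},
                                  n_sets=8, seed=2, set_size=10)
        assert {"g0", "g1"} <= coll.members("RESISTANCE_A")
        assert {"g2", "g3"} <= coll.members("RESISTANCE_B")

    def test_same_seed_identical(self):
        genes = [f"g{i}" for i in range(60)]
        a = generate_gene_sets(genes, {"g1"}, n_sets=6, seed=3)
        b = generate_gene_sets(genes, {"g1"}, n_sets=6, seed=3)
        assert a.sets == b.sets

    def test_random_set_overlap_near_hypergeometric_mean(self):
        """E[|random set ∩ planted|] = set_size * |planted| / N (closed form)."""
        genes = [f"g{i}" for i in range(200)]
        planted = {f"g{i}" for i in range(20)}
        overlaps = []
        for seed in range(30):
            coll = generate_gene_sets(genes, planted, n_sets=12, seed=seed,
                                      set_size=30)
            for sid, (_, members) in coll.sets.items():
                if sid.startswith("RANDOM"):
                    overlaps.append(len(members & planted))
        expected = 30 * 20 / 200  # = 3
        assert abs(np.mean(overlaps) - expected) < 0.5

    def test_too_few_sets_rejected(self):
        with pytest.raises(ResistomeError):
            generate_gene_sets(["g1", "g2", "g3"], {"g1"}, n_sets=1, seed=0)
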