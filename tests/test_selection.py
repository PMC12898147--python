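"""Feature-importance engines and rank aggregation.

Planted-recovery at full pipeline scale (consensus top-5 precision over 20
generator seeds) lives in the acceptance suite; here each engine is checked
on small purpose-built matrices.
"""

import numpy as np
import pytest
from scipy.stats import kendalltau

from resistome.selection import (
    GeneRanking, aggregate_ranks, ga_select, rf_importance, rfe_rank,
    select_core_genes,
)
from resistome.types import ResistomeError


def planted_matrix(seed, n=40, n_noise=5, strength=3.0):
    """One feature tracks the labels at the given strength; rest are noise."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, n_noise + 1))
    X[:, 0] += strength * y
    genes = [f"g{i:02d}" for i in range(n_noise + 1)]
    return X, y, genes


def graded_matrix(seed, n=80):
    """Features with strictly decreasing signal, for stable full rankings."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    strengths = [2.5, 1.8, 1.2, 0.8, 0.4, 0.0]
    X = rng.normal(size=(n, len(strengths)))
    for j, s in enumerate(strengths):
        X[:, j] += s * y
    return X, y, [f"g{j}" for j in range(len(strengths))]


class TestRfImportance:
    def test_planted_feature_ranks_first_across_seeds(self):
        hits = 0
        for seed in range(20):
            X, y, genes = planted_matrix(seed)
            r = rf_importance(X, y, genes, n_iters=50, n_trees=30, seed=seed)
            hits += r.ranks[0] == 1
        assert hits == 20

    def test_importances_average_to_unit_sum(self):
        X, y, genes = planted_matrix(0)
        r = rf_importance(X, y, genes, n_iters=10, n_trees=50, seed=1)
        assert abs(r.scores.sum() - 1.0) < 1e-9

    def test_row_replication_preserves_ranking(self):
        X, y, genes = graded_matrix(2)
        a = rf_importance(X, y, genes, n_iters=40, n_trees=50, seed=5)
        b = rf_importance(np.vstack([X, X]), np.concatenate([y, y]), genes,
                          n_iters=40, n_trees=50, seed=5)
        tau = kendalltau(a.ranks, b.ranks).statistic
        assert tau >= 0.9

    def test_deterministic_under_seed(self):
        X, y, genes = planted_matrix(3)
        a = rf_importance(X, y, genes, n_iters=5, n_trees=20, seed=9)
        b = rf_importance(X, y, genes, n_iters=5, n_trees=20, seed=9)
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.ranks, b.ranks)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ResistomeError):
            rf_importance(X, np.ones(10, int), ["a", "b", "c"], 2, 10, seed=0)


class TestGaSelect:
    def test_planted_feature_has_highest_frequency(self):
        hits = 0
        for seed in range(20):
            X, y, genes = planted_matrix(seed, n=24, n_noise=10)
            r = ga_select(X, y, genes, pop_size=30, n_generations=25,
                          seed=seed, fitness_trees=10)
            hits += r.ranks[0] == 1
        assert hits >= 18

    def test_neutral_drift_keeps_expected_frequency_half(self):
        """With constant fitness and no variation operators, the expected
        inclusion frequency over seeds stays at the init probability 0.5."""
        freqs = []
        for seed in range(20):
            X, y, genes = planted_matrix(seed, n=20, n_noise=5)
            r = ga_select(X, y, genes, pop_size=20, n_generations=10,
                          crossover_rate=0.0, mutation_rate=0.0, seed=seed,
                          fitness_fn=lambda mask: 0.0)
            freqs.append(r.scores)
        mean_freq = np.mean(freqs, axis=0)
        assert np.all(np.abs(mean_freq - 0.5) < 0.15)

    def test_frequencies_are_valid(self):
        X, y, genes = planted_matrix(1, n=20, n_noise=4)
        r = ga_select(X, y, genes, pop_size=10, n_generations=4, seed=2)
        assert np.all((r.scores >= 0) & (r.scores <= 1))
        assert np.any(r.scores > 0)

    def test_deterministic_under_seed(self):
        X, y, genes = planted_matrix(4, n=20, n_noise=4)
        a = ga_select(X, y, genes, pop_size=10, n_generations=4, seed=6)
        b = ga_select(X, y, genes, pop_size=10, n_generations=4, seed=6)
        assert np.array_equal(a.scores, b.scores)

    def test_tiny_population_rejected(self):
        X, y, genes = planted_matrix(0, n=20, n_noise=4)
        with pytest.raises(ResistomeError, match="population"):
            ga_select(X, y, genes, pop_size=1, n_generations=2, seed=0)


class TestRfeRank:
    def test_constant_feature_eliminated_first(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 15)
        X = np.column_stack([3.0 * y + rng.normal(size=30), np.full(30, 2.0)])
        r = rfe_rank(X, y, ["signal", "flat"], step=1, seed=0)
        assert r.ranks.tolist() == [1, 2]

    def test_planted_feature_survives_to_final_round(self):
        hits = 0
        for seed in range(20):
            X, y, genes = planted_matrix(seed, n=30, n_noise=20)
            r = rfe_rank(X, y, genes, step=1, seed=seed)
            hits += r.ranks[0] == 1
        assert hits >= 18

    def test_ranks_are_a_permutation(self):
        X, y, genes = planted_matrix(2, n=30, n_noise=7)
        r = rfe_rank(X, y, genes, step=3, seed=1)
        assert sorted(r.ranks) == list(range(1, len(genes) + 1))

    def test_oversized_step_leaves_one_survivor(self):
        X, y, genes = planted_matrix(3, n=30, n_noise=4)
        r = rfe_rank(X, y, genes, step=99, seed=0)
        assert sorted(r.ranks) == list(range(1, len(genes) + 1))
        assert np.sum(r.ranks == 1) == 1


class TestAggregateRanks:
    @staticmethod
    def _ranking(method, ranks):
        genes = ["A", "B", "C"]
        ranks = np.array(ranks)
        return GeneRanking(method, genes, (4.0 - ranks), ranks)

    def test_hand_computed_mean_ranks(self):
        # gene A gets ranks (1,2,1), B (2,1,3), C (3,3,2)
        r1 = self._ranking("rf", [1, 2, 3])
        r2 = self._ranking("ga", [2, 1, 3])
        r3 = self._ranking("rfe", [1, 3, 2])
        out = aggregate_ranks([r1, r2, r3]).set_index("gene")
        np.testing.assert_allclose(out.loc["A", "mean_rank"], 4 / 3)
        np.testing.assert_allclose(out.loc["B", "mean_rank"], 2.0)
        np.testing.assert_allclose(out.loc["C", "mean_rank"], 8 / 3)
        assert out["final_rank"].tolist() == [1, 2, 3]

    def test_identical_inputs_are_a_fixed_point(self):
        r = self._ranking("rf", [2, 1, 3])
        out = aggregate_ranks([r, self._ranking("ga", [2, 1, 3]),
                               self._ranking("rfe", [2, 1, 3])])
        assert out.sort_values("gene")["mean_rank"].tolist() == [2, 1, 3]

    def test_method_order_irrelevant(self):
        rs = [self._ranking("rf", [1, 2, 3]), self._ranking("ga", [3, 1, 2]),
              self._ranking("rfe", [2, 3, 1])]
        a = aggregate_ranks(rs)[["gene", "mean_rank", "final_rank"]]
        b = aggregate_ranks(rs[::-1])[["gene", "mean_rank", "final_rank"]]
        assert a.equals(b)

    def test_mismatched_gene_sets_listed(self):
        r1 = self._ranking("rf", [1, 2, 3])
        r2 = GeneRanking("ga", ["A", "B", "D"], np.array([3.0, 2, 1]),
                         np.array([1, 2, 3]))
        with pytest.raises(ResistomeError, match="'C', 'D'"):
            aggregate_ranks([r1, r2])

    def test_non_permutation_ranks_rejected(self):
        with pytest.raises(ResistomeError, match="permutation"):
            self._ranking("rfe", [3, 3, 1])

    def test_tie_breaks_lexicographic(self):
        # A and B both have mean rank 1.5 -> A first by gene id
        out = aggregate_ranks([self._ranking("rf", [1, 2, 3]),
                               self._ranking("ga", [2, 1, 3])])
        assert out.iloc[0]["gene"] == "A"


class TestSelectCoreGenes:
    @pytest.fixture()
    def consensus(self):
        r1 = GeneRanking("rf", ["A", "B", "C"], np.array([3.0, 2, 1]),
                         np.array([1, 2, 3]))
        r2 = GeneRanking("ga", ["A", "B", "C"], np.array([3.0, 2, 1]),
                         np.array([1, 2, 3]))
        return aggregate_ranks([r1, r2])

    def test_full_and_single(self, consensus):
        assert select_core_genes(consensus, 3) == ["A", "B", "C"]
        assert select_core_genes(consensus, 1) == ["A"]

    @pytest.mark.parametrize("k", [0, 4])
    def test_out_of_range_rejected(self, consensus, k):
        with pytest.raises(ResistomeError):
            select_core_genes(consensus, k)
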