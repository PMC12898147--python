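"""Consensus feature selection over per-category candidate genes.

Three independent importance engines rank the candidate genes of a drug's
category against that drug's sensitive/resistant labels:

* **rf** — random-forest Gini importance averaged over many stratified
  70/30 train/test iterations (published protocol: 1000 iterations of 500
  trees; tests and small runs scale the iteration count down);
* **ga** — a genetic algorithm over binary gene-inclusion masks whose
  fitness is the ROC AUC of a random forest on a fixed stratified holdout;
  a gene's score is its inclusion frequency across every individual of
  every generation;
* **rfe** — recursive feature elimination driven by a gradient-boosted
  tree classifier (XGBoost), dropping the least important ``step`` features
  per round; rank is the reverse elimination order.

The three rankings are combined by an equal-weight arithmetic mean of ranks
(configurable weights), and the top-k consensus genes are carried forward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from xgboost import XGBClassifier

from .de import log_z_transform
from .types import ExpressionMatrix, ResistomeError, SensitivityTable


@dataclass
class GeneRanking:
    """Per-gene scores and dense ranks (1 = most important) for one method."""

    method: str
    genes: list[str]
    scores: np.ndarray
    ranks: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=int)
        n = len(self.genes)
        if self.scores.shape != (n,) or self.ranks.shape != (n,):
            raise ResistomeError("scores/ranks must align with genes")
        if not np.all(np.isfinite(self.scores)):
            raise ResistomeError("non-finite score")
        if sorted(self.ranks) != list(range(1, n + 1)):
            raise ResistomeError("ranks must be a permutation of 1..n")

    def as_series(self) -> pd.Series:
        return pd.Series(self.ranks, index=self.genes, name=self.method)


def _ranks_from_scores(genes: Sequence[str], scores: np.ndarray) -> np.ndarray:
    """Rank 1 = highest score; ties broken lexicographically by gene id."""
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    ranks = np.empty(len(genes), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def _check_two_classes(y: np.ndarray, min_per_class: int = 2) -> None:
    y = np.asarray(y)
    for lab in (0, 1):
        if int(np.sum(y == lab)) < min_per_class:
            raise ResistomeError(
                f"need at least {min_per_class} samples of class {lab}"
            )


def build_feature_matrix(expr: ExpressionMatrix, sens: SensitivityTable,
                         drug: str, genes: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Normalized-expression feature matrix and labels for one drug.

    Features are the log2(x+1), per-gene z-scored expression values of the
    candidate genes, restricted to cell lines with a sensitivity record for
    the drug. Labels: 1 = resistant.
    """
    genes = list(genes)
    if not genes:
        raise ResistomeError("empty candidate gene list")
    recs = sens.for_drug(drug)
    present = [c for c in expr.cell_line_ids if c in set(recs["cell_line"])]
    cidx = expr.cell_index(present)
    gidx = expr.gene_index(genes)
    X = log_z_transform(expr.counts[cidx])[:, gidx]
    y = sens.labels_for(drug, present)
    _check_two_classes(y, 1)
    return X, y, genes


def rf_importance(X: np.ndarray, y: np.ndarray, genes: Sequence[str],
                  n_iters: int = 1000, n_trees: int = 500,
                  train_frac: float = 0.7, seed: int = 0) -> GeneRanking:
    """Mean Gini importance over repeated stratified train/test iterations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    genes = list(genes)
    _check_two_classes(y)
    rng = np.random.default_rng(seed)
    iter_seeds = rng.integers(0, 2**31 - 1, size=n_iters)
    total = np.zeros(len(genes))
    for s in iter_seeds:
        X_tr, _, y_tr, _ = train_test_split(
            X, y, train_size=train_frac, stratify=y, random_state=int(s)
        )
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(s), n_jobs=1
        )
        clf.fit(X_tr, y_tr)
        total += clf.feature_importances_
    scores = total / n_iters
    return GeneRanking("rf", genes, scores, _ranks_from_scores(genes, scores))


def ga_select(X: np.ndarray, y: np.ndarray, genes: Sequence[str],
              pop_size: int = 50, n_generations: int = 40,
              tournament_k: int = 3, crossover_rate: float = 0.8,
              mutation_rate: float | None = None, seed: int = 0,
              fitness_trees: int = 25, holdout_frac: float = 0.3,
              fitness_fn=None) -> GeneRanking:
    """Genetic-algorithm gene scoring by evolutionary inclusion frequency.

    Chromosomes are binary inclusion masks. Fitness is the ROC AUC of a
    random forest trained on the masked features of a stratified 70 % split
    and evaluated on the remaining 30 % holdout, fixed once per run so
    fitness values are comparable across individuals (and memoizable).
    ``fitness_fn(mask) -> float`` may override the fitness for testing.
    Selection is tournament (size k) with elitism of 1, uniform crossover,
    and independent per-bit mutation (default rate 1/n). All-zero masks are
    repaired by activating one random bit. A gene's score is the fraction
    of all evaluated individuals — every generation including the initial
    population — whose mask includes it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    genes = list(genes)
    n = len(genes)
    if n < 2:
        raise ResistomeError("GA needs at least 2 features")
    if pop_size < 2:
        raise ResistomeError("GA population must have at least 2 individuals")
    _check_two_classes(y)
    if mutation_rate is None:
        mutation_rate = 1.0 / n
    rng = np.random.default_rng(seed)

    if fitness_fn is None:
        split_seed = int(rng.integers(0, 2**31 - 1))
        fit_seed = int(rng.integers(0, 2**31 - 1))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=holdout_frac, stratify=y, random_state=split_seed
        )
        cache: dict[bytes, float] = {}

        def fitness_fn(mask: np.ndarray) -> float:
            key = mask.tobytes()
            if key not in cache:
                clf = RandomForestClassifier(
                    n_estimators=fitness_trees, random_state=fit_seed, n_jobs=1
                )
                clf.fit(X_tr[:, mask], y_tr)
                cache[key] = float(
                    roc_auc_score(y_te, clf.predict_proba(X_te[:, mask])[:, 1])
                )
            return cache[key]

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[rng.integers(0, n)] = True
        return mask

    pop = [repair(rng.random(n) < 0.5) for _ in range(pop_size)]
    inclusion = np.zeros(n)
    n_individuals = 0

    for mask in pop:
        inclusion += mask
    n_individuals += pop_size

    fits = np.array([fitness_fn(m) for m in pop])
    for _ in range(n_generations):
        elite_idx = int(np.argmax(fits))  # first best on ties
        new_pop = [pop[elite_idx].copy()]

        def tournament() -> np.ndarray:
            idx = rng.integers(0, pop_size, size=tournament_k)
            best = idx[int(np.argmax(fits[idx]))]
            return pop[best]

        while len(new_pop) < pop_size:
            p1, p2 = tournament().copy(), tournament().copy()
            if rng.random() < crossover_rate:
                swap = rng.random(n) < 0.5
                c1 = np.where(swap, p2, p1)
                c2 = np.where(swap, p1, p2)
            else:
                c1, c2 = p1, p2
            for child in (c1, c2):
                flip = rng.random(n) < mutation_rate
                child = repair(np.logical_xor(child, flip))
                if len(new_pop) < pop_size:
                    new_pop.append(child)
        pop = new_pop
        for mask in pop:
            inclusion += mask
        n_individuals += pop_size
        fits = np.array([fitness_fn(m) for m in pop])

    scores = inclusion / n_individuals
    return GeneRanking("ga", genes, scores, _ranks_from_scores(genes, scores))


def rfe_rank(X: np.ndarray, y: np.ndarray, genes: Sequence[str],
             step: int = 1, seed: int = 0, n_estimators: int = 50,
             max_depth: int = 3) -> GeneRanking:
    """Recursive feature elimination with a gradient-boosted tree classifier.

    Each round fits the booster on the surviving features and eliminates the
    ``step`` with the lowest importance (ties eliminate the later gene id
    first), until one feature remains. Rank is the reverse elimination
    order: the survivor ranks 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    genes = list(genes)
    n = len(genes)
    if n < 2:
        raise ResistomeError("RFE needs at least 2 features")
    if step < 1:
        raise ResistomeError("step must be >= 1")
    _check_two_classes(y)

    active = list(range(n))
    eliminated: list[int] = []
    while len(active) > 1:
        clf = XGBClassifier(
            n_estimators=n_estimators, max_depth=max_depth,
            random_state=seed, n_jobs=1, tree_method="hist",
            eval_metric="logloss", verbosity=0,
        )
        clf.fit(X[:, active], y)
        imp = clf.feature_importances_
        n_drop = min(step, len(active) - 1)
        # lowest importance first; ties: later gene id eliminated first
        order = sorted(range(len(active)),
                       key=lambda i: (imp[i], tuple(-ord(c) for c in genes[active[i]])))
        drop = sorted((active[i] for i in order[:n_drop]), key=lambda j: genes[j], reverse=True)
        for j in drop:
            eliminated.append(j)
            active.remove(j)
    eliminated.append(active[0])

    ranks = np.empty(n, dtype=int)
    for pos, j in enumerate(eliminated):  # first eliminated = worst
        ranks[j] = n - pos
    scores = (n + 1 - ranks).astype(float)  # survivor highest
    return GeneRanking("rfe", genes, scores, ranks)


def aggregate_ranks(rankings: Sequence[GeneRanking],
                    weights: Sequence[float] | None = None) -> pd.DataFrame:
    """Equal-weight (or weighted) arithmetic mean of method ranks.

    All rankings must cover the identical gene set. Ties in the mean rank
    are broken lexicographically by gene id. Returns a DataFrame indexed by
    final order with columns ``gene, rank_<method>..., mean_rank, final_rank``.
    """
    if not rankings:
        raise ResistomeError("no rankings to aggregate")
    gene_sets = [set(r.genes) for r in rankings]
    base = gene_sets[0]
    for r, gs in zip(rankings[1:], gene_sets[1:]):
        if gs != base:
            diff = sorted(base ^ gs)
            raise ResistomeError(
                f"rankings cover different gene sets; symmetric difference: {diff}"
            )
    if weights is None:
        weights = [1.0] * len(rankings)
    if len(weights) != len(rankings) or sum(weights) <= 0:
        raise ResistomeError("weights must match rankings and sum > 0")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    df = pd.DataFrame({"gene": sorted(base)})
    for r in rankings:
        s = r.as_series()
        df[f"rank_{r.method}"] = df["gene"].map(s).astype(int)
        df[f"score_{r.method}"] = df["gene"].map(
            pd.Series(r.scores, index=r.genes)
        )
    # weighted mean of method ranks; equal weights give the plain average.
    # summation runs in sorted-method order so float rounding cannot make
    # the result depend on the order the rankings were passed in
    mean = np.zeros(len(df))
    for method, wi in sorted(zip([r.method for r in rankings], w)):
        mean = mean + wi * df[f"rank_{method}"].to_numpy()
    df["mean_rank"] = mean
    df = df.sort_values(["mean_rank", "gene"], ignore_index=True)
    df["final_rank"] = np.arange(1, len(df) + 1)
    return df


def select_core_genes(consensus: pd.DataFrame, k: int) -> list[str]:
    """Top-k genes of a consensus ranking, in final-rank order."""
    n = len(consensus)
    if not (1 <= k <= n):
        raise ResistomeError(f"k={k} out of range 1..{n}")
    return consensus.nsmallest(k, "final_rank")["gene"].tolist()
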