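"""Run configuration: every tunable threshold and hyperparameter in one place.

Defaults encode the published analysis settings: DEG thresholds
|log2FC| >= 1 and adjusted p < 0.05; 70 % within-category intersection;
60 % frequency rule for the PPI stage; categories admitted at >= 6 drugs;
random-forest importance averaged over 1000 iterations of 500 trees with a
7:3 stratified split; 5-fold cross-validated grid search scored by ROC AUC.
Settings the original analysis leaves unstated (GA hyperparameters, RFE step,
classifier grid, number of core genes k) carry this package's documented
defaults.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .types import ResistomeError


def _default_grid() -> list[dict]:
    return [
        {"n_estimators": n, "max_depth": d, "min_samples_leaf": leaf}
        for n in (200, 500)
        for d in (None, 8)
        for leaf in (1, 5)
    ]


@dataclass
class RunConfig:
    # DEG calling
    lfc_min: float = 1.0
    padj_max: float = 0.05
    # intersection / network frequency rules
    intersect_frac: float = 0.70
    ppi_frac: float = 0.60
    min_drugs_per_category: int = 6
    min_ppi_score: float = 0.4
    # random-forest importance
    rf_iters: int = 1000
    rf_trees: int = 500
    train_frac: float = 0.7
    # genetic algorithm
    ga_pop_size: int = 50
    ga_generations: int = 40
    ga_tournament_k: int = 3
    ga_crossover_rate: float = 0.8
    ga_mutation_rate: float | None = None  # None -> 1/n_features per bit
    # RFE
    rfe_step: int = 1
    # classifier
    cv_folds: int = 5
    classifier_grid: list = field(default_factory=_default_grid)
    use_smote: bool = True
    undersample: bool = False
    smote_k_neighbors: int = 5
    # consensus
    k_core_genes: int = 20
    # seeds
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("intersect_frac", "ppi_frac", "train_frac"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ResistomeError(f"{name} must be in (0, 1], got {v}")
        if not (0.0 <= self.min_ppi_score <= 1.0):
            raise ResistomeError(f"min_ppi_score must be in [0, 1], got {self.min_ppi_score}")
        for name in (
            "min_drugs_per_category", "rf_iters", "rf_trees", "ga_pop_size",
            "ga_generations", "ga_tournament_k", "rfe_step", "cv_folds",
            "k_core_genes", "smote_k_neighbors",
        ):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ResistomeError(f"{name} must be a positive integer, got {v!r}")
        if not (0.0 <= self.ga_crossover_rate <= 1.0):
            raise ResistomeError("ga_crossover_rate must be in [0, 1]")
        if self.ga_mutation_rate is not None and not (0.0 <= self.ga_mutation_rate <= 1.0):
            raise ResistomeError("ga_mutation_rate must be in [0, 1]")
        if self.lfc_min < 0 or not (0.0 < self.padj_max <= 1.0):
            raise ResistomeError("lfc_min must be >= 0 and padj_max in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticConfig:
    """Study conditions emulated by the synthetic generator."""

    n_cell_lines: int = 100
    n_genes: int = 400
    n_drugs: int = 14
    n_categories: int = 2
    n_core_per_category: int = 5
    effect_lfc: float = 2.0
    dispersion: float = 0.4
    resistant_fraction: float = 0.5
    mode: str = "shared"  # or "per_drug"

    def __post_init__(self) -> None:
        if self.n_cell_lines < 8:
            raise ResistomeError("need at least 8 cell lines")
        if self.n_categories < 1 or self.n_drugs < 2 * self.n_categories:
            raise ResistomeError("need at least 2 drugs per category")
        if not (0.0 < self.resistant_fraction < 1.0):
            raise ResistomeError("resistant_fraction must be in (0, 1)")
        if self.dispersion <= 0:
            raise ResistomeError("dispersion must be positive")
        if self.mode not in ("shared", "per_drug"):
            raise ResistomeError(f"unknown mode {self.mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> tuple[RunConfig, SyntheticConfig]:
    """Load a TOML config file with optional [run] and [synthetic] tables."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    run_kwargs = raw.get("run", {})
    syn_kwargs = raw.get("synthetic", {})
    known_run = set(RunConfig.__dataclass_fields__)
    known_syn = set(SyntheticConfig.__dataclass_fields__)
    problems = [f"[run] unknown key {k!r}" for k in run_kwargs if k not in known_run]
    problems += [f"[synthetic] unknown key {k!r}" for k in syn_kwargs if k not in known_syn]
    if problems:
        raise ResistomeError("config errors: " + "; ".join(problems))
    return RunConfig(**run_kwargs), SyntheticConfig(**syn_kwargs)
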