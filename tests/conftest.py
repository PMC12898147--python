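"""Shared fixtures: one small synthetic dataset reused across test modules."""

import pytest
from hypothesis import settings

from resistome.config import RunConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from resistome.de import deg_gene_set, run_de
from resistome.synth import generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Compact bundle: 60 cell lines, 160 genes, 2 categories x 7 drugs."""
    expr, sens, catalog, truth = generate_dataset(
        n_cell_lines=60, n_genes=160, n_drugs=14, n_categories=2,
        n_core_per_category=5, effect_lfc=2.0, seed=11,
    )
    return expr, sens, catalog, truth


@pytest.fixture(scope="session")
def small_deg_lists(small_dataset):
    """Per-drug significant gene sets for the small bundle."""
    expr, sens, _, _ = small_dataset
    cfg = RunConfig()
    return {d: deg_gene_set(run_de(expr, sens, d, cfg)) for d in sens.drugs}
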