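"""Shared settings for the numbered analysis drivers.

One seed, one output tree (results/), and one configuration: generator
defaults are the study conditions (100 cell lines, 400 genes, 2 drug
categories x 7 drugs, 5 planted core genes per category, effect_lfc = 2);
selector hyperparameters are the reduced sizes used throughout the
validation experiments (50 RF iterations x 500 trees, GA 30 x 25,
RFE step 1).
"""

from pathlib import Path

from resistome.config import RunConfig, SyntheticConfig

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"

RUN_CFG = RunConfig(
    rf_iters=50, rf_trees=500,
    ga_pop_size=30, ga_generations=25,
    classifier_grid=[{"n_estimators": 200, "max_depth": None},
                     {"n_estimators": 200, "max_depth": 8}],
    k_core_genes=5,
    seed=SEED,
)
SYN_CFG = SyntheticConfig()  # the study conditions


def results_dir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
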