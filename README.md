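# resistome

Identification of **core multi-drug-resistance genes** from baseline
transcriptomes and drug-sensitivity screens of cancer cell lines, for
computational biologists studying shared resistance programmes across
pharmacological drug classes.

Given a cell-line × gene count matrix, a table of per-(cell line, drug)
viability log₂ fold changes (log₂FC < 0 → *sensitive*, log₂FC ≥ 0 →
*resistant*), a multi-label drug → category catalog, a STRING-like PPI edge
list, and a GMT gene-set collection, the pipeline runs:

1. **Differential expression** per drug (resistant vs sensitive), using a
   negative-binomial Wald test: median-of-ratios size factors *s*,
   method-of-moments dispersion α (Var = μ + αμ²), per-gene GLM
   log μᵢ = β₀ + β₁·xᵢ + log sᵢ, Wald p on β₁, Benjamini–Hochberg
   adjustment. DEGs: |log₂FC| ≥ 1 and p.adj < 0.05.
2. **Thresholded intersection** within each drug category (admitted at ≥ 6
   drugs): retain genes occurring in ≥ ⌈0.70·m⌉ of the category's m per-drug
   DEG lists; UpSet-style exclusive-intersection counts are exported.
3. **Consensus feature selection** of the retained genes against one drug's
   sensitivity labels, by equal-weight rank averaging of three engines:
   random-forest Gini importance (mean over stratified 7:3 train/test
   iterations), genetic-algorithm inclusion frequency (mask fitness = ROC
   AUC of a random forest on a fixed holdout), and recursive feature
   elimination under a gradient-boosted classifier.
4. **Resistance classification** on the top-k consensus genes: per-fold
   Z-scoring, SMOTE inside training folds, grid-searched random forest under
   stratified 5-fold CV scored by ROC AUC; reports ROC/PR AUC (mean ± sd
   over folds), the pooled confusion matrix at 0.5, and Gini importances.
5. **Network core genes**: genes in ≥ ⌈0.60·m⌉ DEG lists are mapped onto the
   PPI network (edge score ≥ 0.4); genes with betweenness centrality
   strictly above the subnetwork median are core, and their overlap with the
   consensus genes cross-validates the two routes.
6. **Over-representation analysis** of the core genes against the gene-set
   collection: exact hypergeometric upper tail P(X ≥ k), BH-adjusted.

A seeded synthetic-data generator emulates the DepMap-style inputs —
negative-binomial counts, per-drug sensitive/resistant partitions, planted
core/decoy/module genes, a hub-centred PPI graph, planted gene sets — so
every stage has a parameter-recovery test with known ground truth.
See `docs/methods.md` for the model, the generator's design, and all
numerical choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic conditions (100 cell lines × 400 genes, 2 categories × 7 drugs,
5 planted core genes per category, effect log₂FC = 2):

```bash
cd analysis
python 01_simulate.py
python 02_differential_expression.py
python 03_intersect_categories.py
python 04_consensus_selection.py
python 05_classify_resistance.py
python 06_network_core.py
python 07_enrichment.py
```

Selected output (seed 1):

```
CAT0: 15 genes at the 70% threshold (required 5/7 lists); strict intersection across all drugs: 0 genes
CAT0/DRUG000 (5 drugs share this label pattern): top-5 consensus genes ['G0001', 'G0004', 'G0000', 'G0003', 'G0002']
CAT0/DRUG000: ROC AUC 0.998 ± 0.004, PR AUC 0.998 ± 0.004, confusion TP=48 FP=2 TN=48 FN=2
CAT0: 15 nodes, median betweenness 0.00, core genes ['G0000', 'G0001', 'G0002', 'G0003', 'G0004']
  overlap with ML core genes: ['G0000', 'G0001', 'G0002', 'G0003', 'G0004'] (Jaccard 1.00)
CAT0: top set RESISTANCE_CAT0 (k=4/25, p=5.76e-05, padj=0.00115, fold=12.8)
```

Read: the strict all-drug intersection is empty (resistance responses are
partly drug-specific), while the 70 % threshold recovers the 5 planted core
genes plus the 10 weaker shared-signature genes; the consensus ranking puts
exactly the planted genes on top (`G0000`–`G0004`); the classifier built on
them separates resistant from sensitive lines almost perfectly; the network
route independently calls the same genes core; and ORA ranks the planted
resistance set first with ~13-fold enrichment. The second category (CAT1)
recovers 4 of its 5 planted genes by both routes (Jaccard 0.57) — recovery
is strong but not guaranteed gene-by-gene at this effect size.

The same stages are available as a CLI
(`resistome simulate|de|intersect|select|classify|network|enrich|run`),
with `resistome run --out DIR` executing everything end-to-end from one
TOML config and writing a digest manifest for reproducibility.

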