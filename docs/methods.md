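# Methods

## The problem and the data model

Large pharmacogenomic screens measure, for each cancer cell line and each
compound, a viability log₂ fold change under treatment; the sign carries the
phenotype (log₂FC < 0 sensitive, log₂FC ≥ 0 resistant — the boundary is
resistant, and a single shared predicate implements the rule so no stage can
re-implement it differently). Paired with baseline expression counts and a
multi-label drug → pharmacological-category catalog, the question is which
genes mark resistance *consistently across the drugs of a category* rather
than idiosyncratically for one compound. The pipeline treats cell lines as
samples, drugs as repeated noisy probes of a category-level resistance
programme, and genes as features.

Cell lines missing either expression or sensitivity data are dropped with a
logged count (imputation of a missing phenotype is not meaningful here).
Identifier harmonization across sources is an optional two-column mapping
applied at load; unmapped ids are dropped and counted.

## Differential expression: the NB-Wald procedure

Counts are modelled as negative binomial with Var = μ + αμ². Per drug:

* **Size factors** by median-of-ratios: factor_s = median over genes (with
  all-positive counts) of count_gs / geometric-mean_g; if no gene qualifies,
  library-size scaling is used and logged. The method assumes most genes are
  not differentially expressed; when a majority of genes carry signal the
  factors absorb part of it (visible in deliberately extreme toys).
* **Dispersion** per gene by method of moments on normalized counts, pooled
  across the two label groups weighted by degrees of freedom, floored at
  1e-8 and capped at 10. The floor/cap prevent degenerate standard errors;
  ties and zero-information genes fall through to p = 1.
* **GLM** with log link, design = resistant indicator, offset log s_i,
  fitted by IRLS with a closed-form 2×2 solve, vectorized across genes
  (50 iterations max, tolerance 1e-10, natural-log coefficients clamped to
  |β₁| ≤ 15 so one-group-all-zero genes stay finite). The Wald statistic
  β₁/SE(β₁) with SE² = 1/Σw_res + 1/Σw_sens (w = μ/(1+αμ)) gets a
  two-sided normal p. All-zero genes report lfc 0, p 1.
* **Multiplicity** by Benjamini–Hochberg (one shared routine, also used by
  the enrichment stage). DEG: |log₂FC| ≥ 1 (inclusive) and p.adj < 0.05
  (strict), exactly as the thresholds are conventionally printed.

No independent filtering, shrinkage, or outlier-replacement is applied;
the design is the two-group contrast only. The procedure is deliberately a
fully specified, testable substitute for a heavier reference implementation:
its type-I rate on null data is checked to sit in [0.03, 0.07] and its
fold-change recovery against direct NB simulation.

`log_z_transform` (log₂(x+1), then per-gene z-score; constant genes map to
zero) is the normalization used when expression becomes classifier features.

## Intersection rules

"At least f of m lists" is implemented as count ≥ ⌈f·m⌉, which guarantees
the ≥ f reading for every m (float noise at exact products is guarded).
The 70 % rule (candidate genes) and the 60 % rule (network genes) share this
one code path. Drugs whose DEG list is empty stay in the denominator: an
analysis that found nothing is evidence of absence, not missingness.
Direction is ignored at intersection — gene lists, not signed lists, are
intersected. Category admission requires ≥ 6 drugs with usable data.
Exclusive-intersection (UpSet) counts are exported exactly for ≤ 15 lists.

## Consensus feature selection

Per drug, on the category's retained genes, three engines each produce a
full ranking (ties broken lexicographically by gene id, so every ranking is
a permutation):

* **Random forest**: mean Gini importance over stratified 7:3 train/test
  iterations (protocol size 1000 iterations × 500 trees; validation
  experiments use 50 iterations, stated below).
* **Genetic algorithm**: binary inclusion masks; fitness = ROC AUC of a
  random forest on a stratified 30 % holdout fixed once per run (so fitness
  is comparable across individuals and memoizable by mask); tournament
  selection (k = 3), uniform crossover (rate 0.8), per-bit mutation
  (rate 1/n), elitism 1, all-zero masks repaired by switching on one random
  bit. A gene's score is its inclusion frequency over *all* individuals of
  all generations including the initial population. Defaults (population
  50, 40 generations) are this package's choices, as is the AUC fitness;
  the holdout metric matches the classifier stage's criterion.
* **RFE**: iteratively fit a gradient-boosted tree classifier (XGBoost,
  50 rounds, depth 3) and drop the `step` (default 1) least important
  features; rank = reverse elimination order; importance ties eliminate the
  lexicographically later gene first.

Consensus = arithmetic mean of the three ranks with equal weights (a
configurable weight hook exists); the weighted sum is accumulated in
sorted-method order so float rounding cannot make tied means depend on
argument order. Final ties break by gene id. The number of core genes
carried forward, k, is not dictated by anything in the data; the default is
20 (the validation experiments use k = 5, matching their planted count).

Within a category, drugs whose label vectors coincide have identical
feature matrices and labels; the pipeline computes such a group once and
attributes the result to every member.

## Resistance classifier

Stratified 5-fold CV with grid search (default grid: 200/500 trees ×
unbounded/8 depth × 1/5 min-leaf) scored by mean fold ROC AUC, no separate
test set. Z-score statistics come from the training fold only; SMOTE
(synthetic points x + λ(x_nn − x), λ ~ U(0,1), k = 5 minority neighbours)
balances the *training fold only* — oversampling before splitting would
leak synthetic copies of validation points; an optional seeded
majority-undersampling mode exists. Out-of-fold probabilities cover each
sample exactly once; the confusion matrix pools them at threshold 0.5 (no
principled threshold is dictated, 0.5 is the convention); ROC AUC is the
trapezoid over tie-grouped thresholds (equal to the Mann–Whitney statistic
with tie half-credit), PR AUC the trapezoid on the recall grid; both are
reported as mean ± sd over folds. Importances come from one final refit on
the fully balanced data.

## Network core genes

The 60 %-filtered genes are mapped onto the PPI edge list; selected genes
absent from the edge list are reported unmapped and excluded (they have no
topology), while genes whose every edge fails the confidence gate
(score ≥ 0.4, the conventional medium-confidence cutoff, inclusive) remain
as degree-0 nodes. Edges are unweighted for shortest paths — confidence
gates existence only. Betweenness is the unnormalized unordered-pair form;
core genes lie strictly above the subnetwork median (even node counts use
the midpoint; an all-tied subnetwork therefore has no core genes, and the
median is over the induced subnetwork, not the full PPI). The intersection
and Jaccard index against the consensus genes quantify the agreement of the
two routes.

## Over-representation analysis

Exact hypergeometric upper tail P(X ≥ k) per gene set, BH across tested
sets; sets disjoint from the universe are skipped, query genes outside the
universe dropped and counted. The universe defaults to the genes of the
expression matrix — the background actually tested — not the union of the
GMT. Both a p < 0.05 view and an unfiltered top-N view are reported, since
enrichment summaries are often read under a deliberately relaxed threshold.
Fold enrichment (k/n)/(K/N) equals 1 exactly at parity. The test is
discrete: at small set sizes the attainable level at "p < 0.05" is well
below 0.05, which the calibration experiment accounts for by computing the
exact expectation.

## The synthetic generator

The generator emulates what the pipeline assumes about screen data, with
planted ground truth for parameter recovery:

* **Counts**: shared baseline expression (one matrix for all drugs, as
  baseline expression is measured once per cell line), gene means
  log-normal (median ≈ 55 counts), per-cell library factors log-normal
  (sd 0.15), NB sampling at per-gene dispersion (default α = 0.4, a
  realistic biological CV across cell lines; α < 1e-6 falls back to
  Poisson). A `per_drug` mode draws an independent matrix per drug with
  effects applied literally to that drug's resistant lines.
* **Labels**: each category has a *consensus* resistant cell-line set used
  by ⌈0.7·m⌉ of its m drugs and an independent *minority* set used by the
  rest; log₂FC magnitudes are nuisance draws, the sign carries the label,
  and every drug is checked to have both classes. With one shared
  expression matrix, "a gene carries the effect under a fraction of drugs"
  can only be realized through which drugs key their labels to which cell
  set — per-drug independent labels would make a shared per-drug effect
  impossible.
* **Planted genes per category** (400 genes, 5 core per category by
  default): *core* genes, elevated 2^effect (default effect 2) in
  consensus-resistant lines — DE for exactly the ≥ 70 % consensus drugs and
  hubs of the PPI graph; *decoys*, elevated only in minority-resistant
  lines — DE for < 70 % of drugs, which the intersection must exclude; and
  *module* genes (one per hub per category), elevated at 0.9·effect with
  high dispersion (α = 1.5) in consensus-resistant lines. Module genes make
  the emulated DEG lists richer than the bare planted set — real per-drug
  lists contain weaker shared responders — and they are what gives the
  60 %-filtered PPI subnetwork non-hub nodes: the above-median rule is
  vacuous on a subnetwork containing only hubs, since half of any set lies
  at or below its median. Their high dispersion keeps them individually
  weaker classifier features than core genes (≈1.3σ vs ≈2.4σ separation on
  the log scale), so consensus selection can rank core above module genes
  while both pass the DEG thresholds.
* **PPI**: hubs (the planted core genes) are chained; every other gene
  attaches to a hub in deterministic round-robin order — the guarantee
  mechanism that makes hubs high-degree, high-betweenness centres in every
  seed — plus, once ≥ 4 nodes exist, a preferential-attachment extra edge
  with probability 0.4 for scale-free texture. Structural edges carry
  confidence scores in [0.6, 1], extras in [0.2, 1], so the 0.4 gate is
  actually exercised. Module count = total hub count per category, so
  round-robin gives every hub one same-category module neighbour.
* **Gene sets**: one planted "resistance" set per category (≥ 80 % of that
  category's core genes plus filler to 25 members) among otherwise random
  25-gene sets; the universe is the full gene list.

With effect 0 every planted elevation (including modules) vanishes and the
dataset is an exact null. All outputs are bit-reproducible under a seed.

**What the generator does not emulate**: lineage/batch structure,
dose–response shape, correlated gene modules beyond the planted signature,
gene-length or GC effects, and any real gene identity. Passing recovery
tests therefore demonstrate that the pipeline's machinery recovers the
structure it targets under its own statistical assumptions — not that the
discovered genes of any real screen are correct.

## Validation experiments and problem sizes

* **Oracle agreement**: betweenness vs exhaustive shortest-path enumeration
  (50 random graphs, n ≤ 8, 1e-9); BH vs the classical step-up rejection
  rule (200 random p-vectors; the step-up condition is compared in its
  rescaled form p·m/k ≤ t so knife-edge thresholds agree under floating
  point); hypergeometric tail vs exact fraction sums (1e-12); trapezoid ROC
  AUC vs the pairwise U statistic (200-point instances, 1e-12).
* **Calibration**: DE type-I rate on a null dataset (2000 genes, 50 vs 50)
  in [0.03, 0.07] with ≈ 0 post-BH DEG calls; label-permutation classifier
  AUC centred on 0.5 ± 0.07 (20 permutations); ORA flag rate at p < 0.05
  on random queries compared against the exactly computed discrete
  expectation (sets of 40 in a universe of 400, 200 replicates).
* **Recovery** at the default study conditions (100 cell lines, 400 genes,
  2 categories × 7 drugs, 5 core genes, effect 2) over 20 seeds, with
  reduced selector sizes chosen once for the experiment: RF 50 iterations ×
  500 trees, GA 30 × 25 with 15-tree fitness forests, RFE step 1, a
  single-point classifier grid (200 trees), k = 5. The selection +
  classifier block is evaluated on one category per seed (alternating),
  giving 20 independent measurements; intersection, network, and ORA checks
  cover both categories every seed.
* **Determinism**: the full pipeline run twice at one master seed on a
  reduced configuration (40 cell lines, 120 genes, small selector sizes —
  determinism does not depend on size) must produce identical SHA-256
  digests for every output file. Sub-seeds derive from the master seed via
  a counter scheme keyed by stage name and a CRC of the item id, so adding
  a drug leaves other drugs' results untouched.

## Known limitations

* The NB-Wald stand-in omits shrinkage and outlier handling; on real data
  its DEG lists will differ at the margins from heavier reference tools
  (the downstream consensus machinery does not depend on those internals).
* Consensus drugs within a category sharing identical labels is a synthetic
  simplification; real categories have correlated but unequal label
  patterns, making per-drug DEG lists overlap partially rather than
  coincide.
* GA hyperparameters and fitness are package choices; the inclusion
  frequency is denominator-sensitive (all generations including the initial
  population, by definition here).
* The betweenness median rule is sensitive to the size and composition of
  the induced subnetwork; very small subnetworks make "above median"
  unstable, which is why the generator plants module genes.
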