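# Methods

## The prediction problem

A *bilocus variant combination* is a set of one or two variant alleles in
each of two genes, considered jointly as a candidate cause of an
oligogenic disease. Curated disease-causing combinations number only in
the hundreds, while combinations sampled from population sequencing data
— presumed neutral — can be generated essentially without limit. The
reference training design couples 301 curated positives with 150,500
neutral combinations (a 1:500 imbalance), and any useful classifier must
hold its false-positive density very low because applications generate
combinations combinatorially.

`bilocus` implements that design as a reusable library: feature
encoding, a balanced random forest, gene-pair-aware cross-validation,
confidence-zone calibration, and the two relatedness features that
require their own machinery (knowledge-graph distance, GO similarity).

## Feature encoding

Each combination is encoded as a fixed-layout numeric vector. The
production layout has 15 features: four per-allele CADD raw scores
(`CADD1`..`CADD4`), per-gene haploinsufficiency (`HIPred_A/B`),
inheritance-specific pathogenicity (`ISPP_AD_A/B`, `ISPP_AR_A/B`,
`ISPP_XL_A`), selection pressure (`dN_dS_A`), and three gene-pair
features (`Biol_Dist`, `BP_sim`, `KG_distance`). A 20-feature layout
appends `ISPP_XL_B`, `dN_dS_B`, `Coexp`, `MF_sim`, `CC_sim` and exists
for the feature-selection experiment.

Ordering makes slots comparable across combinations: gene A is the more
intolerant gene (lower RVIS), and within a gene the allele with the
higher CADD score fills slot 1. Two rules are our own choices where the
ordering is otherwise undefined: a gene with missing RVIS is treated as
the least intolerant (assigned B), and exact ties fall back to
lexicographic identifiers so the encoding is deterministic.

Two kinds of absent values are distinguished. *Structurally
uncomputable* values get sentinels outside the feature's informative
range: a wild-type second allele's CADD slot is −3, and the X-linked
ISPP score of an autosomal gene is −0.5. *Merely missing* values are
imputed with the mean of the feature's positive-class and
negative-class medians, computed on observed values only; sentinel-coded
entries are excluded from the medians and are never overwritten. The
imputer is fit on training data only and serialized inside the model
artifact to prevent leakage. When a feature is never observed in one
class (possible in small cross-validation folds, e.g. no X-linked gene
among a fold's positives), the strict contract raises; pipeline code
passes `strict=False`, which substitutes the observed class's median —
a documented fallback, not the default.

## Knowledge-graph distance

The knowledge graph mixes node types (Gene, Pathway, GOTerm,
ProteinFamily, Complex, Disease, TissueCoexpCluster) with unit-weight
edges. The distance between two genes is the shortest-path edge count
divided by the number of distinct node types on the path, endpoints
included: two genes co-member of one pathway score 2/2 = 1, a direct
PPI pair scores 1/1 = 1. Where several minimum-length paths carry
different type counts the reported value is the minimum ratio (the path
with the most types), computed by dynamic programming over the BFS
shortest-path DAG with subset-dominance pruning — deterministic and
independent of path enumeration order. Disconnected pairs propagate as
missing values and are imputed downstream. Whether disease nodes should
be traversable is not specified anywhere authoritative; we allow all
node types on paths.

## GO similarity

Per sub-ontology (BP, MF, CC), term information content is estimated
from the supplied annotation corpus with descendant propagation:
IC(t) = −log p(t), where p(t) is the fraction of annotated genes whose
propagated annotations contain t. The namespace root has IC 0 and IC is
monotone from root to leaf; a term no corpus gene maps to receives the
namespace's maximal observed IC (that of a singleton annotation), which
preserves the monotonicity. A term annotated to *every* gene has IC 0
like the root, so by the 0/0 → 0 convention it scores 0 even against
itself — self-similarity of a gene is exactly 1 only when its terms all
carry positive IC. Term-term similarity is SimGIC over
reflexive ancestor sets (shared-ancestor IC sum over union IC sum);
gene-gene similarity is the best-match average of the term-level
matrix. Composing a groupwise measure (SimGIC) with a pairwise
aggregator (BMA) is an interpretation — the combination is
underspecified in the tooling this mirrors — and is documented as such.
A gene with no annotation in a namespace yields a missing similarity
(imputed downstream), not 0, since "unknown" is not "dissimilar".

## Balanced random forest

Each of the (default 400) trees trains on a balanced bootstrap: a
with-replacement sample of the minority class of size n_min plus an
equally sized with-replacement sample of the majority class. Trees are
CART with Gini splitting, depth capped at 10, and √d candidate features
per split; no pruning beyond the depth cap. The forest probability is
the unweighted mean over trees of the leaf class-1 fraction, which
yields the smooth score distributions that average precision and zone
calibration need. Classification uses probability ≥ threshold (boundary
positive), default 0.5.

Reproducibility: a master seed spawns per-tree seed sequences, so
results are bit-identical across runs and independent of execution
order. The per-tree class counts are logged in the model and asserted
in tests.

Two comparison structures support model-structure experiments: a plain
forest trained once on a 1:1 down-sample of the majority class, and an
ensemble of independently subsampled forests with averaged
probabilities. Both share the probability contract.

The model artifact is a joblib document carrying a schema version
string, the forest configuration, the feature layout, the fitted
imputer and the trees; loading verifies the version.

## Wrapper feature selection

Feature subsets over the 20-feature layout are searched by
random-restart stochastic hill climbing. The objective is the mean
positive-class F1 of a k-fold cross-validated random forest on a
balanced candidate set restricted to the subset. Each step draws a
fixed number of random single-bit-flip neighbors and moves only on
strict improvement of the incumbent (steepest ascent among the sampled
neighbors); a restart ends after a fixed number of consecutive
non-improving steps. Objective values are memoized by bitmask. The
reference profile (10,000 restarts, 10 neighbors, 100 stability steps,
5-fold CV of a 100-tree forest on a 301:301 sample) is the stored
default; tests exercise scaled profiles. Tie-breaks (smaller
cardinality, then smaller bitmask) make results deterministic per seed.

## Evaluation

Metrics are per-class precision, recall, specificity, F1 and the
geometric mean of the two recalls, aggregated weighted by support;
0/0 ratios are defined as 0. Cross-validation is leave-one-group-out
with gene pairs as groups: each fold holds out every instance of one
pair, the imputer and forest are refit on the remainder, and metrics
are computed once on the pooled out-of-fold predictions (not averaged
per fold). Folds are ordered by sorted pair key for reproducibility; a
fold whose training side loses a class entirely is skipped with a
logged warning.

Confidence zones translate probability thresholds into an expected
false-positive density among neutral inputs. Calibration is pure order
statistics on a held-out neutral set: the threshold for density d is
the smallest probability t such that the fraction of calibration
probabilities ≥ t is at most d. By construction the bound holds exactly
on the calibration set. Thresholds are floored at the 0.5
classification boundary by default (a zone below it would be
meaningless); `floor=0.0` exposes the raw order statistic. The
published thresholds (0.5 / 0.743 / 0.891 for classification / 99% /
99.9%) ship as documented defaults for users without a calibration
set; they derive from the original 10,000-combination neutral set and
are not reproducible from synthetic data.

## Interpretation

Global: per tree, each internal node's weighted Gini impurity decrease
is credited to its split feature and per-tree totals are normalized to
sum to 1; the forest view is the per-feature distribution over trees.
Local: each tree's prediction decomposes into the root's class-1
fraction (bias) plus, along the decision path, the change in class-1
fraction at each node credited to that node's split feature; bias plus
contributions equals the tree's probability exactly, and forest means
preserve the identity. Contributions are reported on the probability
scale, matching `predict_proba`.

## Synthetic data

The generator emulates the *structure* of the training design, not its
biology. Features are drawn per class from clipped Gaussians whose
neutral means sit at plausible population values (modest CADD, distant
weakly-similar pairs) and whose positive means shift most on the lead
CADD scores and the gene-pair relatedness features; `effect_scale`
interpolates between identical distributions (0) and the default
separation (1). Missingness is MCAR at a configurable rate (default
5%); single-variant genes (default 50%) and autosomal genes (default
95%) inject the two sentinels. The default imbalance ratio is the
reference 1:500; tests pass smaller ratios explicitly for runtime.
Gene pairs are drawn from a finite pool so leave-one-group-out
cross-validation has genuine group structure.

What this does *not* emulate: correlated features, linkage and
site-frequency structure, annotation biases, or any real gene network
topology. Passing tests therefore demonstrate that the machinery is
correct and that the model recovers planted signal under known
conditions — not that any particular real-data performance level would
be reached.

Companion generators produce population-like variant records for the
neutral-set pre-filter (reject MAF > 3.5%, intronic variants, and
synonymous variants more than 195 nt from an exon boundary), typed
knowledge graphs with planted pathway/PPI motifs and one isolated gene,
and small random ontologies with annotation corpora. Exclusion of
combinations overlapping a positive set is implemented at the
combination level (the original procedure removed whole carriers; the
combination is the testable unit).

## Test problem sizes

Simulation-backed tests use desk-scale profiles chosen once: the
planted-recovery experiment plants 3 informative features (one-SD-class
shift 1.2) among 20 with 100 instances per class and searches with 3
restarts, 10 neighbors per step, 7 stability steps and a 3-fold CV of a
20-tree forest, repeated over 20 seeded runs; the strong-separation
cross-validation cohort uses 50 positives at 1:100 over 100 gene pairs
with 50-tree forests; the null cohort uses 30 positives at 1:50 with
`effect_scale=0`. These sizes are the package's own test profile and
are recorded here so they can be scaled up verbatim.

## Known limitations

- The exact published model, its 15-feature selection and its
  thresholds depend on the real curated/population training data and
  annotation resources, which this package deliberately does not fetch;
  it reproduces the method, not the fitted artifact.
- The SimGIC/BMA composition and the hill-climbing move rule are
  documented interpretations of underspecified procedures.
- The knowledge-graph distance DP is exponential in pathological graphs
  with very many equal-length paths of diverse types; fine at the graph
  sizes used here.
- Annotation retrieval (CADD, HIPred, ISPP, dN/dS, coexpression,
  biological distance) is out of scope: inputs arrive pre-annotated.
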