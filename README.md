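# bilocus

Pathogenicity prediction for **bilocus (digenic) variant combinations**:
one or two variant alleles in each of two genes, classified jointly as
*disease-causing* or *neutral*.

Oligogenic diseases arise from the joint effect of variants in a small
number of genes. Curated disease-causing combinations are rare (a few
hundred), while neutral combinations sampled from population data are
effectively unlimited, so the learning problem is binary classification
under extreme class imbalance (the reference design uses 1 positive per
500 negatives). `bilocus` is aimed at method developers and
bioinformaticians who need the full pipeline as a tested library:
feature encoding, the classifier, imbalance-aware evaluation, and
calibrated decision thresholds.

## The model

Each combination is encoded as a fixed 15-feature vector after
canonical ordering (more intolerant gene — lower RVIS — first; higher
CADD allele first):

- variant level: CADD raw scores `CADD1..CADD4` (wild-type second
  allele slot = −3);
- gene level: `HIPred_A/B`, `ISPP_AD_A/B`, `ISPP_AR_A/B`, `ISPP_XL_A`
  (−0.5 for autosomal genes), `dN_dS_A`;
- gene-pair level: `Biol_Dist`, `BP_sim` (SimGIC + best-match average
  GO similarity), `KG_distance`.

Missing values are imputed with the mean of the two class medians,
fitted on training data only. The classifier is a **balanced random
forest**: each of 400 Gini trees of depth ≤ 10 trains on a bootstrap of
the minority class plus an equally sized with-replacement sample of the
majority class, and the predicted probability is the mean leaf
class-1 fraction,

  p(x) = (1/T) · Σ_t f_t(x),  classify disease-causing iff p ≥ 0.5.

The gene-pair **knowledge-graph distance** is the shortest-path edge
count between two gene nodes in a heterogeneous typed graph divided by
the number of distinct node types on the path: pathway co-membership
gives 2/2 = 1, a direct PPI edge gives 1/1 = 1.

Evaluation is per-class precision / recall / specificity / F1 /
geometric mean with support weighting, leave-one-group-out
cross-validation stratified by gene pair, and confidence zones whose
probability thresholds bound the expected false-positive density among
neutral inputs (99% zone ⇒ ≤ 1% FPs, 99.9% zone ⇒ ≤ 0.1% FPs).

See `docs/methods.md` for assumptions, parameter defaults and design
choices.

## Worked example

```sh
bilocus simulate --out-dir demo --n-positive 10 --ratio 10 --seed 4
bilocus train --combinations demo/cohort.tsv --model-out demo/model.joblib \
              --n-trees 20 --seed 1
bilocus predict --model demo/model.joblib --combinations demo/cohort.tsv \
                --out demo/pred.tsv
head -4 demo/pred.tsv
```

prints

```
gene_a_id	gene_b_id	probability	class	zone
GENE0002	GENE0006	0.95	disease_causing	99.9%
GENE0000	GENE0005	0.9	disease_causing	99.9%
GENE0004	GENE0010	0.8	disease_causing	99%
```

Each row carries the forest probability, the 0.5-threshold class, and
the confidence zone under the documented default thresholds
(0.743 / 0.891); with `bilocus calibrate` you can replace those with
thresholds calibrated on your own neutral set. The first rows are the
simulated disease-causing combinations, so probabilities near 1 are the
expected behavior on this separable synthetic cohort.

The same library surface is available from Python
(`bilocus.feature_model`, `bilocus.balanced_forest`,
`bilocus.evaluation`, `bilocus.kg_distance`, `bilocus.go_similarity`,
`bilocus.feature_search`, `bilocus.interpretation`,
`bilocus.synthetic_data`).

## Combination TSV format

Tab-separated, UTF-8, `.` or empty cell = missing. One row per
combination with columns: `gene_a_id`, `gene_b_id`; per-gene
annotations `rvis_{a,b}`, `hipred_{a,b}`, `ispp_ad_{a,b}`,
`ispp_ar_{a,b}`, `ispp_xl_{a,b}`, `dn_ds_{a,b}`, `is_x_linked_{a,b}`;
per-allele `variant_{a,b}{1,2}`, `cadd_{a,b}{1,2}` (leave the second
slot empty for a single variant); pair features `biol_dist`, `bp_sim`,
`mf_sim`, `cc_sim`, `coexp`, `kg_distance`; and `label`
(`disease_causing` / `neutral` / `unknown`).

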