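"""Synthetic fixtures for every pipeline stage.

Real training data for this problem couple a few hundred curated
disease-causing bilocus combinations with hundreds of thousands of
presumed-neutral combinations sampled from population sequencing data
(a 1:500 class imbalance), annotated from a dozen external resources.
None of that is redistributable at desk scale, so this module generates
structurally faithful stand-ins:

* labeled cohorts of annotated combinations whose features are drawn
  from per-class clipped Gaussians, with configurable class separation,
  MCAR missingness, and the two structural sentinels (single-variant
  genes, autosomal genes) injected at configurable rates;
* population-like variant records (MAF, consequence class, distance to
  the nearest exon boundary) for exercising the neutral-set pre-filter;
* typed knowledge graphs with planted pathway-membership and PPI
  structure;
* small random ontologies with gene annotation corpora.

All generators are deterministic per seed.  The default imbalance ratio
is the 1:500 of the reference training design; tests use smaller
ratios for runtime, via the spec, not by changing defaults here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .feature_model import (
    FULL20,
    AlleleAnnotation,
    BilocusCombination,
    FeatureLayout,
    FULL20_LAYOUT,
    GeneAnnotation,
    PairAnnotation,
)
from .go_similarity import AnnotationCorpus, Ontology, NAMESPACES
from .kg_distance import build_graph

import networkx as nx

# Per-feature (neutral mean, positive mean, sd, lower clip, upper clip).
# Neutral baselines sit where population-derived combinations typically
# fall (modest CADD, distant weakly-similar gene pairs); the positive
# shifts concentrate on the features reported as the strongest signals
# (the lead CADD score of each gene and the gene-pair relatedness
# measures), with milder shifts elsewhere.
DEFAULT_FEATURE_SPECS: dict[str, tuple[float, float, float, float, float]] = {
    "CADD1": (2.5, 4.5, 1.5, -10.0, 50.0),
    "CADD2": (1.0, 2.0, 1.5, -10.0, 50.0),
    "CADD3": (2.0, 3.8, 1.5, -10.0, 50.0),
    "CADD4": (0.8, 1.5, 1.5, -10.0, 50.0),
    "HIPred_A": (0.35, 0.55, 0.2, 0.0, 1.0),
    "HIPred_B": (0.35, 0.5, 0.2, 0.0, 1.0),
    "ISPP_AD_A": (0.3, 0.45, 0.15, 0.0, 1.0),
    "ISPP_AD_B": (0.3, 0.42, 0.15, 0.0, 1.0),
    "ISPP_AR_A": (0.3, 0.4, 0.15, 0.0, 1.0),
    "ISPP_AR_B": (0.3, 0.38, 0.15, 0.0, 1.0),
    "ISPP_XL_A": (0.3, 0.38, 0.15, 0.0, 1.0),
    "ISPP_XL_B": (0.3, 0.35, 0.15, 0.0, 1.0),
    "dN_dS_A": (0.28, 0.2, 0.12, 0.0, 3.0),
    "dN_dS_B": (0.28, 0.22, 0.12, 0.0, 3.0),
    "Biol_Dist": (9.0, 5.5, 2.5, 0.0, 30.0),
    "Coexp": (0.1, 0.3, 0.25, -1.0, 1.0),
    "BP_sim": (0.25, 0.5, 0.18, 0.0, 1.0),
    "MF_sim": (0.25, 0.4, 0.18, 0.0, 1.0),
    "CC_sim": (0.25, 0.4, 0.18, 0.0, 1.0),
    "KG_distance": (2.2, 1.2, 0.7, 0.0, 10.0),
}


@dataclass(frozen=True)
class CohortSpec:
    n_positive: int = 50
    imbalance_ratio: int = 500
    effect_scale: float = 1.0  # 0 -> identical class distributions
    missingness: float = 0.05
    non_x_fraction: float = 0.95
    single_variant_fraction: float = 0.5
    n_gene_pairs: Optional[int] = None  # default: one pool pair per 2 records
    feature_specs: Mapping[str, tuple[float, float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_SPECS)
    )
    seed: int = 0

    def __post_init__(self):
        if self.imbalance_ratio < 1:
            raise ValueError("imbalance_ratio must be >= 1")
        for name in ("missingness", "non_x_fraction", "single_variant_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_positive < 1:
            raise ValueError("n_positive must be >= 1")


def _draw_features(
    spec: CohortSpec, positive: bool, rng: np.random.Generator
) -> dict[str, float]:
    out = {}
    for feat in FULL20:
        neg_mu, pos_mu, sd, lo, hi = spec.feature_specs[feat]
        mu = neg_mu + spec.effect_scale * (pos_mu - neg_mu) if positive else neg_mu
        out[feat] = float(np.clip(rng.normal(mu, sd), lo, hi))
    return out


def gen_cohort(
    spec: CohortSpec,
) -> tuple[list[BilocusCombination], list[BilocusCombination]]:
    """Generate (positives, negatives) with counts n_positive and
    n_positive * imbalance_ratio."""
    rng = np.random.default_rng(spec.seed)
    n_neg = spec.n_positive * spec.imbalance_ratio
    n_pairs = spec.n_gene_pairs or max(2, (spec.n_positive + n_neg) // 2)
    # gene pool with per-gene intolerance scores fixed across the cohort
    n_genes = max(4, int(np.ceil((1 + np.sqrt(1 + 8 * n_pairs)) / 2)))
    gene_ids = [f"GENE{i:04d}" for i in range(n_genes)]
    rvis = {g: float(rng.normal(0.0, 1.0)) for g in gene_ids}
    all_pairs = [(a, b) for i, a in enumerate(gene_ids) for b in gene_ids[i + 1:]]
    pool_idx = rng.choice(len(all_pairs), size=min(n_pairs, len(all_pairs)), replace=False)
    pair_pool = [all_pairs[i] for i in pool_idx]

    positives = [_gen_combination(spec, True, pair_pool, rvis, rng, i)
                 for i in range(spec.n_positive)]
    negatives = [_gen_combination(spec, False, pair_pool, rvis, rng, spec.n_positive + i)
                 for i in range(n_neg)]
    return positives, negatives


def _maybe(rng: np.random.Generator, rate: float, value: float) -> Optional[float]:
    return None if rng.random() < rate else value


def _gen_combination(
    spec: CohortSpec,
    positive: bool,
    pair_pool: Sequence[tuple[str, str]],
    rvis: Mapping[str, float],
    rng: np.random.Generator,
    serial: int,
) -> BilocusCombination:
    feats = _draw_features(spec, positive, rng)
    m = spec.missingness
    g1, g2 = pair_pool[int(rng.integers(len(pair_pool)))]
    # assign the A-features to the more intolerant (lower RVIS) gene so
    # the drawn values land in the intended slots after ordering
    ga_id, gb_id = sorted((g1, g2), key=lambda g: (rvis[g], g))

    def gene(gene_id: str, side: str) -> GeneAnnotation:
        x_linked = rng.random() >= spec.non_x_fraction
        return GeneAnnotation(
            gene_id=gene_id,
            rvis=rvis[gene_id],
            hipred=_maybe(rng, m, feats[f"HIPred_{side}"]),
            ispp_ad=_maybe(rng, m, feats[f"ISPP_AD_{side}"]),
            ispp_ar=_maybe(rng, m, feats[f"ISPP_AR_{side}"]),
            ispp_xl=_maybe(rng, m, feats[f"ISPP_XL_{side}"]) if x_linked else None,
            dn_ds=_maybe(rng, m, feats[f"dN_dS_{side}"]),
            is_x_linked=x_linked,
        )

    def alleles(side: str) -> tuple[AlleleAnnotation, ...]:
        c1, c2 = feats[f"CADD{1 if side == 'A' else 3}"], feats[f"CADD{2 if side == 'A' else 4}"]
        hi, lo = max(c1, c2), min(c1, c2)
        first = AlleleAnnotation(f"var{serial}{side}1", cadd_raw=hi)
        if rng.random() < spec.single_variant_fraction:
            return (first,)
        return (first, AlleleAnnotation(f"var{serial}{side}2", cadd_raw=lo))

    pair = PairAnnotation(
        biol_dist=_maybe(rng, m, feats["Biol_Dist"]),
        bp_sim=_maybe(rng, m, feats["BP_sim"]),
        mf_sim=_maybe(rng, m, feats["MF_sim"]),
        cc_sim=_maybe(rng, m, feats["CC_sim"]),
        coexp=_maybe(rng, m, feats["Coexp"]),
        kg_distance=_maybe(rng, m, feats["KG_distance"]),
    )
    return BilocusCombination(
        gene_a=gene(ga_id, "A"),
        gene_b=gene(gb_id, "B"),
        alleles_a=alleles("A"),
        alleles_b=alleles("B"),
        pair=pair,
        label="disease_causing" if positive else "neutral",
    )


def gen_feature_matrices(
    spec: CohortSpec, layout: FeatureLayout = FULL20_LAYOUT
) -> tuple[np.ndarray, np.ndarray]:
    """Fully numeric per-class matrices (no missingness or sentinels) —
    the vector-level view of the cohort for model-layer experiments."""
    rng = np.random.default_rng(spec.seed)
    n_neg = spec.n_positive * spec.imbalance_ratio

    def draw(n: int, positive: bool) -> np.ndarray:
        rows = [
            [_draw_features(spec, positive, rng)[f] for f in layout.features]
            for _ in range(n)
        ]
        return np.array(rows)

    return draw(spec.n_positive, True), draw(n_neg, False)


# ---------------------------------------------------------------------------
# population-like variant records and the neutral-set pre-filter
# ---------------------------------------------------------------------------

CONSEQUENCES = ("missense", "synonymous", "intronic", "other")

#: Pre-filter constants for candidate neutral variants: rare (MAF at or
#: below 3.5%), non-intronic, and synonymous only when within 195 nt of
#: an exon boundary.
MAF_CUTOFF = 0.035
SYNONYMOUS_BOUNDARY_NT = 195


@dataclass(frozen=True)
class VariantRecord:
    variant_id: str
    maf: float
    consequence: str
    distance_to_exon_boundary: int

    def __post_init__(self):
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError("maf must be in [0, 1]")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.distance_to_exon_boundary < 0:
            raise ValueError("distance_to_exon_boundary must be >= 0")


def variant_prefilter(v: VariantRecord) -> bool:
    """Keep a candidate neutral variant?  Pure predicate."""
    if v.maf > MAF_CUTOFF:
        return False
    if v.consequence == "intronic":
        return False
    if v.consequence == "synonymous" and v.distance_to_exon_boundary > SYNONYMOUS_BOUNDARY_NT:
        return False
    return True


def gen_variants(n: int, seed: int = 0) -> list[VariantRecord]:
    """Random variant records spanning the pre-filter's regimes."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(VariantRecord(
            variant_id=f"v{i:05d}",
            maf=float(rng.beta(0.5, 8.0)),
            consequence=CONSEQUENCES[int(rng.integers(len(CONSEQUENCES)))],
            distance_to_exon_boundary=int(rng.integers(0, 400)),
        ))
    return out


@dataclass(frozen=True)
class PopulationSpec:
    individuals_per_group: int = 5
    groups: tuple[str, ...] = ("AFR", "AMR", "EAS", "EUR", "SAS")


@dataclass(frozen=True)
class Individual:
    individual_id: str
    group: str
    gene_variants: Mapping[str, tuple[VariantRecord, ...]]  # gene -> pool


@dataclass(frozen=True)
class NeutralDraw:
    individual_id: str
    pair_key: tuple[str, str]
    variants_a: tuple[str, ...]
    variants_b: tuple[str, ...]

    @property
    def combination_key(self) -> tuple:
        return (self.pair_key, tuple(sorted(self.variants_a + self.variants_b)))


def gen_population(
    spec: PopulationSpec, n_genes: int = 30, variants_per_gene: int = 4, seed: int = 0
) -> list[Individual]:
    """Individuals balanced across groups, each with per-gene variant
    pools that already pass the pre-filter."""
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    candidates = [v for v in gen_variants(40 * n_genes, seed=seed + 1) if variant_prefilter(v)]
    out = []
    k = 0
    for group in spec.groups:
        for i in range(spec.individuals_per_group):
            pools = {}
            for g in genes:
                take = rng.choice(len(candidates), size=variants_per_gene, replace=False)
                pools[g] = tuple(candidates[t] for t in take)
            out.append(Individual(f"{group}{i:03d}", group, pools))
            k += 1
    return out


def sample_neutral_combinations(
    individuals: Sequence[Individual],
    n_per_individual: int = 1,
    exclusion: Iterable[tuple] = (),
    seed: int = 0,
) -> list[NeutralDraw]:
    """One random gene pair with 1-2 random variants per gene, per draw.

    Draws whose combination key appears in ``exclusion`` are rejected
    and redrawn, emulating the removal of combinations overlapping the
    positive set.  Balanced across individuals by construction.
    """
    rng = np.random.default_rng(seed)
    excluded = set(exclusion)
    out = []
    for ind in individuals:
        genes = sorted(ind.gene_variants)
        if len(genes) < 2:
            raise ValueError(f"individual {ind.individual_id} has fewer than 2 genes")
        for _ in range(n_per_individual):
            for attempt in range(1000):
                i, j = rng.choice(len(genes), size=2, replace=False)
                ga, gb = sorted((genes[i], genes[j]))

                def pick(g: str) -> tuple[str, ...]:
                    pool = ind.gene_variants[g]
                    k = int(rng.integers(1, min(2, len(pool)) + 1))
                    take = rng.choice(len(pool), size=k, replace=False)
                    return tuple(sorted(pool[t].variant_id for t in take))

                draw = NeutralDraw(ind.individual_id, (ga, gb), pick(ga), pick(gb))
                if draw.combination_key not in excluded:
                    out.append(draw)
                    break
            else:
                raise RuntimeError("variant pools exhausted under exclusion list")
    return out


# ---------------------------------------------------------------------------
# knowledge graphs and ontologies
# ---------------------------------------------------------------------------


def gen_knowledge_graph(
    n_genes: int = 12,
    n_pathways: int = 3,
    n_terms: int = 5,
    edge_density: float = 0.15,
    seed: int = 0,
) -> nx.Graph:
    """Typed random graph with planted structure.

    GENE_PW_1 and GENE_PW_2 share membership in pathway PW_SHARED (and
    nothing else); GENE_PPI_1 and GENE_PPI_2 share one direct PPI edge;
    GENE_ISOLATED has no edges.  Remaining genes, pathways and ontology
    terms are wired randomly at ``edge_density``.
    """
    if n_genes < 1 or n_pathways < 1 or n_terms < 0:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    planted_genes = ["GENE_PW_1", "GENE_PW_2", "GENE_PPI_1", "GENE_PPI_2", "GENE_ISOLATED"]
    free_genes = [f"G{i:03d}" for i in range(n_genes)]
    pathways = ["PW_SHARED"] + [f"PW{i:03d}" for i in range(n_pathways)]
    terms = [f"T{i:03d}" for i in range(n_terms)]

    nodes = (
        [(g, "Gene") for g in planted_genes + free_genes]
        + [(p, "Pathway") for p in pathways]
        + [(t, "GOTerm") for t in terms]
    )
    edges = [
        ("GENE_PW_1", "PW_SHARED", "membership"),
        ("GENE_PW_2", "PW_SHARED", "membership"),
        ("GENE_PPI_1", "GENE_PPI_2", "PPI"),
    ]
    # random wiring among the free nodes only, so the planted examples
    # and the isolated gene stay exact
    free_nodes = free_genes + pathways[1:] + terms
    for i, u in enumerate(free_nodes):
        for v in free_nodes[i + 1:]:
            if rng.random() < edge_density:
                relation = "membership" if "PW" in u + v or "T" in u + v else "PPI"
                edges.append((u, v, relation))
    return build_graph(nodes, edges)


def gen_ontology_corpus(
    n_terms: int = 20,
    depth: int = 3,
    n_genes: int = 10,
    seed: int = 0,
    namespaces: Sequence[str] = NAMESPACES,
) -> tuple[Ontology, AnnotationCorpus]:
    """Random rooted is_a DAG per namespace plus random gene annotations.

    ``depth=1`` yields a star: every non-root term's only ancestor is
    the zero-IC root, so sibling similarities are exactly 0.
    """
    if n_terms < 1 or depth < 1 or n_genes < 1:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    parents: dict[str, list[str]] = {}
    namespace: dict[str, str] = {}
    leaves_by_ns: dict[str, list[str]] = {}
    for ns in namespaces:
        tag = ns.split("_")[0].upper()[:2]
        root = f"{tag}:ROOT"
        parents[root] = []
        namespace[root] = ns
        levels = [[root]]
        made = 0
        per_level = max(1, n_terms // depth)
        for lvl in range(1, depth + 1):
            level_terms = []
            n_here = per_level if lvl < depth else max(1, n_terms - (depth - 1) * per_level)
            for i in range(n_here):
                t = f"{tag}:{lvl:02d}{i:03d}"
                n_parents = 1 if lvl == 1 else int(rng.integers(1, min(2, len(levels[lvl - 1])) + 1))
                take = rng.choice(len(levels[lvl - 1]), size=n_parents, replace=False)
                parents[t] = [levels[lvl - 1][k] for k in take]
                namespace[t] = ns
                level_terms.append(t)
            levels.append(level_terms)
            made += n_here
        leaves_by_ns[ns] = levels[-1]

    ontology = Ontology(parents, namespace)
    gene_terms: dict[str, set[str]] = {}
    for i in range(n_genes):
        gene = f"GENE{i:04d}"
        terms: set[str] = set()
        for ns in namespaces:
            pool = [t for t in ontology.terms(ns) if t != f"{ns.split('_')[0].upper()[:2]}:ROOT"]
            k = int(rng.integers(1, min(3, len(pool)) + 1))
            take = rng.choice(len(pool), size=k, replace=False)
            terms |= {pool[j] for j in take}
        gene_terms[gene] = terms
    return ontology, AnnotationCorpus(ontology, gene_terms)
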