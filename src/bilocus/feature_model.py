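"""Data model for bilocus variant combinations and their feature encoding.

A bilocus combination carries one or two variant alleles in each of two
genes, plus annotations at the variant level (CADD raw scores), the gene
level (HIPred, ISPP AD/AR/XL, dN/dS, RVIS) and the gene-pair level
(biological distance, GO similarities, coexpression, knowledge-graph
distance).  Before a combination can be scored it is put into canonical
order (more intolerant gene first, more deleterious allele first) and
encoded as a fixed-layout, fully numeric feature vector with documented
sentinel values for structurally uncomputable entries and median-based
imputation for values that are merely missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Sentinel for the CADD slot of a wild-type (absent second) allele.
#: Chosen outside CADD's informative raw range.
CADD_WILDTYPE_SENTINEL = -3.0

#: Sentinel for the X-linked ISPP score of an autosomal gene, outside
#: the informative [0, 1] range.
ISPP_XL_SENTINEL = -0.5

PRODUCTION15 = (
    "CADD1", "CADD2", "CADD3", "CADD4",
    "HIPred_A", "HIPred_B",
    "ISPP_AD_A", "ISPP_AD_B", "ISPP_AR_A", "ISPP_AR_B",
    "ISPP_XL_A", "dN_dS_A", "Biol_Dist", "BP_sim", "KG_distance",
)

FULL20 = PRODUCTION15 + ("ISPP_XL_B", "dN_dS_B", "Coexp", "MF_sim", "CC_sim")

#: Features whose sentinel codes must be excluded from imputation medians
#: and must never be overwritten by the imputer.
_SENTINEL_OF = {
    "CADD1": CADD_WILDTYPE_SENTINEL,
    "CADD2": CADD_WILDTYPE_SENTINEL,
    "CADD3": CADD_WILDTYPE_SENTINEL,
    "CADD4": CADD_WILDTYPE_SENTINEL,
    "ISPP_XL_A": ISPP_XL_SENTINEL,
    "ISPP_XL_B": ISPP_XL_SENTINEL,
}


@dataclass(frozen=True)
class FeatureLayout:
    """Fixed ordering of feature names for vector encoding."""

    name: str
    features: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.features)

    def index(self, feature: str) -> int:
        return self.features.index(feature)


PRODUCTION15_LAYOUT = FeatureLayout("production15", PRODUCTION15)
FULL20_LAYOUT = FeatureLayout("full20", FULL20)

LAYOUTS = {"production15": PRODUCTION15_LAYOUT, "full20": FULL20_LAYOUT}


@dataclass(frozen=True)
class AlleleAnnotation:
    """One variant allele; ``is_wildtype`` marks the absent second allele."""

    variant_id: str
    cadd_raw: Optional[float] = None
    is_wildtype: bool = False

    @classmethod
    def wildtype(cls) -> "AlleleAnnotation":
        return cls(variant_id="WT", cadd_raw=None, is_wildtype=True)


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    rvis: Optional[float] = None
    hipred: Optional[float] = None
    ispp_ad: Optional[float] = None
    ispp_ar: Optional[float] = None
    ispp_xl: Optional[float] = None
    dn_ds: Optional[float] = None
    is_x_linked: bool = False


@dataclass(frozen=True)
class PairAnnotation:
    biol_dist: Optional[float] = None
    bp_sim: Optional[float] = None
    mf_sim: Optional[float] = None
    cc_sim: Optional[float] = None
    coexp: Optional[float] = None
    kg_distance: Optional[float] = None


@dataclass(frozen=True)
class BilocusCombination:
    """Two genes with 1-2 variant alleles each, optionally labeled."""

    gene_a: GeneAnnotation
    gene_b: GeneAnnotation
    alleles_a: tuple[AlleleAnnotation, ...]
    alleles_b: tuple[AlleleAnnotation, ...]
    pair: PairAnnotation = field(default_factory=PairAnnotation)
    label: str = "unknown"  # disease_causing | neutral | unknown
    source_meta: Optional[Mapping[str, object]] = None
    ordered: bool = False

    def __post_init__(self):
        for alleles in (self.alleles_a, self.alleles_b):
            if not 1 <= len(alleles) <= 2:
                raise ValueError("each gene carries 1-2 variant alleles")
        if self.label not in ("disease_causing", "neutral", "unknown"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def pair_key(self) -> tuple[str, str]:
        """Canonical unordered gene-id pair, invariant under gene order."""
        return tuple(sorted((self.gene_a.gene_id, self.gene_b.gene_id)))


def _rvis_sort_key(gene: GeneAnnotation) -> tuple[float, str]:
    # Missing RVIS sorts last (treated as least intolerant); gene_id
    # breaks exact ties deterministically.
    rvis = gene.rvis if gene.rvis is not None else math.inf
    return (rvis, gene.gene_id)


def _cadd_sort_key(allele: AlleleAnnotation) -> tuple[float, str]:
    # Higher CADD first; wild-type / missing CADD sorts last.
    if allele.is_wildtype or allele.cadd_raw is None:
        cadd = -math.inf
    else:
        cadd = allele.cadd_raw
    return (-cadd, allele.variant_id)


def order_combination(c: BilocusCombination) -> BilocusCombination:
    """Return the canonically ordered copy of a combination.

    Gene A is the more intolerant gene (lower RVIS; missing RVIS counts
    as least intolerant; ties broken by gene id).  Within each gene the
    allele with the higher CADD raw score is slot 1, and a single-variant
    gene receives a wild-type second slot.  Idempotent and
    label-preserving.
    """
    genes = sorted(
        [(c.gene_a, c.alleles_a), (c.gene_b, c.alleles_b)],
        key=lambda ga: _rvis_sort_key(ga[0]),
    )

    def pad(alleles: Sequence[AlleleAnnotation]) -> tuple[AlleleAnnotation, ...]:
        ordered = sorted(alleles, key=_cadd_sort_key)
        if len(ordered) == 1:
            ordered.append(AlleleAnnotation.wildtype())
        return tuple(ordered)

    (ga, aa), (gb, ab) = genes
    return replace(
        c, gene_a=ga, gene_b=gb, alleles_a=pad(aa), alleles_b=pad(ab), ordered=True
    )


def raw_feature_row(c: BilocusCombination, layout: FeatureLayout) -> dict[str, float]:
    """Map an ordered combination to raw feature values.

    Sentinels are applied here (wild-type CADD slots and the ISPP_XL
    score of autosomal genes); everything else that is unannotated stays
    NaN for downstream imputation.
    """
    if not c.ordered:
        raise ValueError("combination must be ordered before encoding")

    def cadd(allele: AlleleAnnotation) -> float:
        if allele.is_wildtype:
            return CADD_WILDTYPE_SENTINEL
        return np.nan if allele.cadd_raw is None else float(allele.cadd_raw)

    def opt(v: Optional[float]) -> float:
        return np.nan if v is None else float(v)

    def ispp_xl(g: GeneAnnotation) -> float:
        if not g.is_x_linked:
            return ISPP_XL_SENTINEL
        return opt(g.ispp_xl)

    kg = c.pair.kg_distance
    if kg is not None and math.isinf(kg):
        kg = None  # unreachable gene pair -> missing, imputed downstream

    values = {
        "CADD1": cadd(c.alleles_a[0]),
        "CADD2": cadd(c.alleles_a[1]),
        "CADD3": cadd(c.alleles_b[0]),
        "CADD4": cadd(c.alleles_b[1]),
        "HIPred_A": opt(c.gene_a.hipred),
        "HIPred_B": opt(c.gene_b.hipred),
        "ISPP_AD_A": opt(c.gene_a.ispp_ad),
        "ISPP_AD_B": opt(c.gene_b.ispp_ad),
        "ISPP_AR_A": opt(c.gene_a.ispp_ar),
        "ISPP_AR_B": opt(c.gene_b.ispp_ar),
        "ISPP_XL_A": ispp_xl(c.gene_a),
        "ISPP_XL_B": ispp_xl(c.gene_b),
        "dN_dS_A": opt(c.gene_a.dn_ds),
        "dN_dS_B": opt(c.gene_b.dn_ds),
        "Biol_Dist": opt(c.pair.biol_dist),
        "Coexp": opt(c.pair.coexp),
        "BP_sim": opt(c.pair.bp_sim),
        "MF_sim": opt(c.pair.mf_sim),
        "CC_sim": opt(c.pair.cc_sim),
        "KG_distance": opt(kg),
    }
    return {f: values[f] for f in layout.features}


@dataclass(frozen=True)
class ImputationModel:
    """Per-feature fill values: mean of the two class medians.

    ``provenance`` records the (positive median, negative median) pair
    behind each fill value.  Medians are computed on observed values
    only — NaN and sentinel-coded entries are excluded.
    """

    layout: FeatureLayout
    fill: Mapping[str, float]
    provenance: Mapping[str, tuple[float, float]]

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for feat in self.layout.features:
            out[feat] = out[feat].fillna(self.fill[feat])
        return out


def combinations_frame(
    combinations: Iterable[BilocusCombination], layout: FeatureLayout
) -> pd.DataFrame:
    """Raw (sentinel-coded, NaN-for-missing) feature table, one row each."""
    rows = [raw_feature_row(order_combination(c), layout) for c in combinations]
    return pd.DataFrame(rows, columns=list(layout.features))


def fit_imputer(
    positives: pd.DataFrame | Iterable[BilocusCombination],
    negatives: pd.DataFrame | Iterable[BilocusCombination],
    layout: FeatureLayout = PRODUCTION15_LAYOUT,
    strict: bool = True,
) -> ImputationModel:
    """Fit per-feature fill values from the two training classes.

    The fill value for a feature is the arithmetic mean of the feature's
    median in the positive class and its median in the negative class,
    each computed over observed (non-missing, non-sentinel) values.
    With ``strict=True`` (default) a feature never observed in a class
    raises ``ValueError`` naming the feature and class; with
    ``strict=False`` the observed class's median stands in for the
    unobserved one (used by cross-validation folds, where small minority
    classes can lack rare annotations such as X-linked scores).
    """
    pos = positives if isinstance(positives, pd.DataFrame) else combinations_frame(positives, layout)
    neg = negatives if isinstance(negatives, pd.DataFrame) else combinations_frame(negatives, layout)

    fill: dict[str, float] = {}
    prov: dict[str, tuple[float, float]] = {}
    for feat in layout.features:
        medians: list[Optional[float]] = []
        for cls_name, frame in (("positive", pos), ("negative", neg)):
            col = frame[feat]
            if feat in _SENTINEL_OF:
                col = col[col != _SENTINEL_OF[feat]]
            col = col.dropna()
            if col.empty:
                if strict:
                    raise ValueError(
                        f"feature {feat!r} never observed in the {cls_name} class"
                    )
                medians.append(None)
            else:
                medians.append(float(col.median()))
        observed = [m for m in medians if m is not None]
        if not observed:
            if feat in _SENTINEL_OF:
                observed = [_SENTINEL_OF[feat]]
            else:
                raise ValueError(f"feature {feat!r} never observed in either class")
        medians = [m if m is not None else observed[0] for m in medians]
        prov[feat] = (medians[0], medians[1])
        fill[feat] = (medians[0] + medians[1]) / 2.0
    return ImputationModel(layout=layout, fill=fill, provenance=prov)


def vectorize(
    c: BilocusCombination,
    imputer: ImputationModel,
    layout: Optional[FeatureLayout] = None,
) -> np.ndarray:
    """Encode one ordered combination as a fully numeric feature vector."""
    layout = layout or imputer.layout
    row = raw_feature_row(c, layout)
    return np.array(
        [row[f] if not math.isnan(row[f]) else imputer.fill[f] for f in layout.features]
    )


def vectorize_all(
    combinations: Sequence[BilocusCombination],
    imputer: ImputationModel,
    layout: Optional[FeatureLayout] = None,
) -> np.ndarray:
    layout = layout or imputer.layout
    frame = combinations_frame(combinations, layout)
    return imputer.transform(frame).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# TSV input
# ---------------------------------------------------------------------------

_GENE_COLS = ("rvis", "hipred", "ispp_ad", "ispp_ar", "ispp_xl", "dn_ds")
_PAIR_COLS = ("biol_dist", "bp_sim", "mf_sim", "cc_sim", "coexp", "kg_distance")

#: Documented TSV header (README).  Per-gene columns carry _a/_b
#: suffixes; allele columns are variant_id/cadd with gene+slot suffixes.
COMBINATION_COLUMNS = (
    ("gene_a_id", "gene_b_id")
    + tuple(f"{c}_a" for c in _GENE_COLS) + ("is_x_linked_a",)
    + tuple(f"{c}_b" for c in _GENE_COLS) + ("is_x_linked_b",)
    + ("variant_a1", "cadd_a1", "variant_a2", "cadd_a2",
       "variant_b1", "cadd_b1", "variant_b2", "cadd_b2")
    + _PAIR_COLS
    + ("label",)
)


class CombinationFormatError(ValueError):
    """Malformed combination TSV; message carries the offending row."""


def _cell(row: pd.Series, col: str) -> Optional[float]:
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v in ("", "."):
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        raise CombinationFormatError(f"non-numeric value {v!r} in column {col!r}")


def _bool_cell(row: pd.Series, col: str) -> bool:
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v in ("", "."):
        return False
    return str(v).strip().lower() in ("1", "true", "yes")


def read_combinations(path, n_alleles_max: int = 2) -> list[BilocusCombination]:
    """Read a combination TSV ("." or empty cell = missing)."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    # Overflow allele columns are tolerated at the schema level so that a
    # row carrying 3 alleles for one gene fails with its line number.
    overflow = {"variant_a3", "cadd_a3", "variant_b3", "cadd_b3"}
    unknown = set(table.columns) - set(COMBINATION_COLUMNS) - overflow
    if unknown:
        raise CombinationFormatError(f"unknown columns: {sorted(unknown)}")

    out = []
    for i, row in table.iterrows():
        lineno = i + 2  # header is line 1
        try:
            combo = _parse_row(row)
        except CombinationFormatError as exc:
            raise CombinationFormatError(f"line {lineno}: {exc}") from None
        out.append(combo)
    return out


def _parse_row(row: pd.Series) -> BilocusCombination:
    def gene(suffix: str) -> GeneAnnotation:
        return GeneAnnotation(
            gene_id=str(row[f"gene_{suffix}_id"]),
            rvis=_cell(row, f"rvis_{suffix}"),
            hipred=_cell(row, f"hipred_{suffix}"),
            ispp_ad=_cell(row, f"ispp_ad_{suffix}"),
            ispp_ar=_cell(row, f"ispp_ar_{suffix}"),
            ispp_xl=_cell(row, f"ispp_xl_{suffix}"),
            dn_ds=_cell(row, f"dn_ds_{suffix}"),
            is_x_linked=_bool_cell(row, f"is_x_linked_{suffix}"),
        )

    def alleles(suffix: str) -> tuple[AlleleAnnotation, ...]:
        found = []
        for slot in (1, 2, 3):  # probe one past the limit to catch overfull rows
            vid = row.get(f"variant_{suffix}{slot}", "")
            if vid not in ("", "."):
                if slot > 2:
                    raise CombinationFormatError(
                        f"more than 2 variant alleles for gene {suffix.upper()}"
                    )
                found.append(
                    AlleleAnnotation(variant_id=str(vid), cadd_raw=_cell(row, f"cadd_{suffix}{slot}"))
                )
        if not found:
            raise CombinationFormatError(f"no variant allele for gene {suffix.upper()}")
        return tuple(found)

    pair = PairAnnotation(**{c: _cell(row, c) for c in _PAIR_COLS})
    label = str(row.get("label", "") or "unknown")
    if label in ("", "."):
        label = "unknown"
    return BilocusCombination(
        gene_a=gene("a"), gene_b=gene("b"),
        alleles_a=alleles("a"), alleles_b=alleles("b"),
        pair=pair, label=label,
    )


def write_combinations(combinations: Sequence[BilocusCombination], path) -> None:
    """Write combinations as the documented TSV (inverse of read_combinations)."""
    rows = []
    for c in combinations:
        row: dict[str, object] = {}
        for suffix, g in (("a", c.gene_a), ("b", c.gene_b)):
            row[f"gene_{suffix}_id"] = g.gene_id
            for col in _GENE_COLS:
                row[f"{col}_{suffix}"] = getattr(g, col)
            row[f"is_x_linked_{suffix}"] = int(g.is_x_linked)
        for suffix, alleles in (("a", c.alleles_a), ("b", c.alleles_b)):
            for slot, al in enumerate(alleles, start=1):
                if al.is_wildtype:
                    continue
                row[f"variant_{suffix}{slot}"] = al.variant_id
                row[f"cadd_{suffix}{slot}"] = al.cadd_raw
        for col in _PAIR_COLS:
            row[col] = getattr(c.pair, col)
        row["label"] = c.label
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(COMBINATION_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, na_rep=".")
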