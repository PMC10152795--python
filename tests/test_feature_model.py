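"""Combination ordering, sentinel encoding, imputation and TSV IO."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bilocus import feature_model as fm
from bilocus import synthetic_data as sd
from bilocus.feature_model import (
    AlleleAnnotation,
    BilocusCombination,
    GeneAnnotation,
    PairAnnotation,
    order_combination,
)


def combo(rvis_a=-0.7, rvis_b=1.3, gene_a="GA", gene_b="GB",
          cadds_a=(25.1,), cadds_b=(3.2, 7.7), x_linked_a=False, label="unknown"):
    return BilocusCombination(
        gene_a=GeneAnnotation(gene_a, rvis=rvis_a, hipred=0.5, ispp_ad=0.4,
                              ispp_ar=0.3, dn_ds=0.2, is_x_linked=x_linked_a),
        gene_b=GeneAnnotation(gene_b, rvis=rvis_b, hipred=0.6, ispp_ad=0.5,
                              ispp_ar=0.2, dn_ds=0.25),
        alleles_a=tuple(AlleleAnnotation(f"va{i}", cadd_raw=c) for i, c in enumerate(cadds_a)),
        alleles_b=tuple(AlleleAnnotation(f"vb{i}", cadd_raw=c) for i, c in enumerate(cadds_b)),
        pair=PairAnnotation(biol_dist=5.0, bp_sim=0.4, mf_sim=0.3, cc_sim=0.2,
                            coexp=0.1, kg_distance=1.5),
        label=label,
    )


class TestOrdering:
    def test_lower_rvis_gene_becomes_a(self):
        c = order_combination(combo(rvis_a=1.3, rvis_b=-0.7, gene_a="X", gene_b="Y"))
        assert c.gene_a.gene_id == "Y"
        assert c.gene_a.rvis == -0.7

    def test_higher_cadd_allele_first_and_wildtype_padding(self):
        c = order_combination(combo(cadds_a=(3.2,), cadds_b=(3.2, 25.1)))
        assert c.alleles_b[0].cadd_raw == 25.1
        assert c.alleles_a[1].is_wildtype  # single-variant gene padded

    def test_equal_rvis_breaks_ties_lexicographically(self):
        c = order_combination(combo(rvis_a=0.5, rvis_b=0.5, gene_a="ZZZ", gene_b="AAA"))
        assert c.gene_a.gene_id == "AAA"

    def test_missing_rvis_gene_goes_last(self):
        c = order_combination(combo(rvis_a=None, rvis_b=2.0))
        assert c.gene_a.rvis == 2.0

    def test_idempotent_and_label_preserving(self):
        c1 = order_combination(combo(label="neutral"))
        c2 = order_combination(c1)
        assert c1 == c2
        assert c2.label == "neutral"
        assert c2.pair_key == combo().pair_key

    @settings(max_examples=50, derandomize=True)
    @given(
        rvis_a=st.floats(-3, 3), rvis_b=st.floats(-3, 3),
        cadd_a=st.floats(-5, 40), cadd_b1=st.floats(-5, 40),
        cadd_b2=st.floats(-5, 40),
    )
    def test_ordering_invariants_hold_for_arbitrary_scores(
            self, rvis_a, rvis_b, cadd_a, cadd_b1, cadd_b2):
        c = order_combination(combo(rvis_a=rvis_a, rvis_b=rvis_b,
                                    cadds_a=(cadd_a,), cadds_b=(cadd_b1, cadd_b2)))
        assert c.gene_a.rvis <= c.gene_b.rvis
        for alleles in (c.alleles_a, c.alleles_b):
            if not alleles[1].is_wildtype:
                assert alleles[0].cadd_raw >= alleles[1].cadd_raw
            assert not alleles[0].is_wildtype  # padding fills slot 2 only
        assert order_combination(c) == c  # idempotent

    def test_gene_swap_yields_identical_vector(self):
        c = combo()
        swapped = BilocusCombination(
            gene_a=c.gene_b, gene_b=c.gene_a,
            alleles_a=c.alleles_b, alleles_b=c.alleles_a,
            pair=c.pair, label=c.label,
        )
        imp = _toy_imputer()
        v1 = fm.vectorize(order_combination(c), imp)
        v2 = fm.vectorize(order_combination(swapped), imp)
        np.testing.assert_array_equal(v1, v2)


def _toy_imputer():
    rows = pd.DataFrame({f: [0.5, 0.6] for f in fm.FULL20})
    return fm.fit_imputer(rows, rows, fm.FULL20_LAYOUT)


class TestImputer:
    def test_mean_of_class_medians(self):
        pos = pd.DataFrame({f: [0.4, 0.4, 0.4] for f in fm.PRODUCTION15})
        neg = pd.DataFrame({f: [0.2, 0.2] for f in fm.PRODUCTION15})
        imp = fm.fit_imputer(pos, neg)
        assert imp.fill["HIPred_A"] == pytest.approx(0.3)

    def test_identical_distributions_give_common_median(self):
        frame = pd.DataFrame({f: [0.1, 0.7, 0.9] for f in fm.PRODUCTION15})
        imp = fm.fit_imputer(frame, frame.copy())
        assert imp.fill["CADD1"] == pytest.approx(0.7)

    def test_matches_bruteforce_median_oracle(self):
        rng = np.random.default_rng(42)
        pos = pd.DataFrame(rng.normal(1, 1, (25, 15)), columns=list(fm.PRODUCTION15))
        neg = pd.DataFrame(rng.normal(0, 1, (25, 15)), columns=list(fm.PRODUCTION15))
        pos.iloc[rng.integers(0, 25, 10), rng.integers(0, 15, 10)] = np.nan
        imp = fm.fit_imputer(pos, neg)
        for feat in fm.PRODUCTION15:
            def med(frame):
                vals = sorted(v for v in frame[feat] if not math.isnan(v)
                              and v != fm._SENTINEL_OF.get(feat))
                n = len(vals)
                return vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2
            assert imp.fill[feat] == pytest.approx((med(pos) + med(neg)) / 2, abs=1e-12)

    def test_sentinels_excluded_from_medians(self):
        pos = pd.DataFrame({f: [0.4, 0.6] for f in fm.PRODUCTION15})
        pos["ISPP_XL_A"] = [fm.ISPP_XL_SENTINEL, 0.8]
        neg = pd.DataFrame({f: [0.2, 0.2] for f in fm.PRODUCTION15})
        imp = fm.fit_imputer(pos, neg)
        assert imp.fill["ISPP_XL_A"] == pytest.approx((0.8 + 0.2) / 2)

    def test_unobserved_feature_errors_with_name(self):
        pos = pd.DataFrame({f: [np.nan, np.nan] for f in fm.PRODUCTION15})
        neg = pd.DataFrame({f: [0.2, 0.2] for f in fm.PRODUCTION15})
        with pytest.raises(ValueError, match="CADD1.*positive"):
            fm.fit_imputer(pos, neg)

    def test_nonstrict_falls_back_to_observed_class(self):
        pos = pd.DataFrame({f: [0.4] for f in fm.PRODUCTION15})
        pos["HIPred_A"] = [np.nan]
        neg = pd.DataFrame({f: [0.2, 0.2] for f in fm.PRODUCTION15})
        imp = fm.fit_imputer(pos, neg, strict=False)
        assert imp.fill["HIPred_A"] == pytest.approx(0.2)


class TestVectorize:
    def test_wildtype_slot_gets_cadd_sentinel(self):
        c = order_combination(combo(cadds_a=(25.1,)))
        v = fm.vectorize(c, _toy_imputer(), fm.FULL20_LAYOUT)
        assert v[fm.FULL20_LAYOUT.index("CADD2")] == fm.CADD_WILDTYPE_SENTINEL

    def test_autosomal_gene_gets_ispp_xl_sentinel(self):
        c = order_combination(combo(x_linked_a=False))
        v = fm.vectorize(c, _toy_imputer(), fm.FULL20_LAYOUT)
        assert v[fm.FULL20_LAYOUT.index("ISPP_XL_A")] == fm.ISPP_XL_SENTINEL

    def test_fully_annotated_combination_is_identity(self):
        c = order_combination(combo(cadds_a=(25.1, 1.0)))
        v = fm.vectorize(c, _toy_imputer(), fm.FULL20_LAYOUT)
        lay = fm.FULL20_LAYOUT
        assert v[lay.index("CADD1")] == 25.1
        assert v[lay.index("Biol_Dist")] == 5.0
        assert v[lay.index("KG_distance")] == 1.5

    def test_unordered_input_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            fm.vectorize(combo(), _toy_imputer(), fm.FULL20_LAYOUT)

    def test_vector_never_contains_missing(self):
        spec = sd.CohortSpec(n_positive=10, imbalance_ratio=5, missingness=0.3, seed=3)
        pos, neg = sd.gen_cohort(spec)
        imp = fm.fit_imputer(pos, neg, fm.FULL20_LAYOUT, strict=False)
        X = fm.vectorize_all(pos + neg, imp)
        assert not np.isnan(X).any()
        assert X.shape == (len(pos) + len(neg), 20)


class TestTsvIO:
    def test_roundtrip(self, tmp_path):
        pos, neg = sd.gen_cohort(sd.CohortSpec(n_positive=3, imbalance_ratio=2, seed=9))
        path = tmp_path / "combos.tsv"
        fm.write_combinations(pos + neg, path)
        back = fm.read_combinations(path)
        assert len(back) == len(pos) + len(neg)
        assert [c.pair_key for c in back] == [c.pair_key for c in pos + neg]
        assert [c.label for c in back] == [c.label for c in pos + neg]

    def test_well_formed_rows_parse(self, tmp_path):
        pos, _ = sd.gen_cohort(sd.CohortSpec(n_positive=3, imbalance_ratio=1, seed=1))
        path = tmp_path / "c.tsv"
        fm.write_combinations(pos, path)
        assert len(fm.read_combinations(path)) == 3

    def test_three_alleles_in_one_gene_rejected_with_line(self, tmp_path):
        pos, _ = sd.gen_cohort(sd.CohortSpec(n_positive=1, imbalance_ratio=1, seed=1))
        path = tmp_path / "c.tsv"
        fm.write_combinations(pos, path)
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        table["variant_a3"] = ["vx"]
        table["cadd_a3"] = ["5.0"]
        table.to_csv(path, sep="\t", index=False)
        with pytest.raises(fm.CombinationFormatError, match="line 2"):
            fm.read_combinations(path)

    def test_empty_cell_becomes_missing(self, tmp_path):
        pos, _ = sd.gen_cohort(sd.CohortSpec(n_positive=1, imbalance_ratio=1,
                                             missingness=0.0, seed=1))
        path = tmp_path / "c.tsv"
        fm.write_combinations(pos, path)
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        table.loc[0, "hipred_a"] = ""
        table.to_csv(path, sep="\t", index=False)
        back = fm.read_combinations(path)
        assert back[0].gene_a.hipred is None or back[0].gene_b.hipred is None

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        pos, _ = sd.gen_cohort(sd.CohortSpec(n_positive=1, imbalance_ratio=1, seed=1))
        fm.write_combinations(pos, path)
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        table["bogus"] = ["1"]
        table.to_csv(path, sep="\t", index=False)
        with pytest.raises(fm.CombinationFormatError, match="bogus"):
            fm.read_combinations(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        pos, _ = sd.gen_cohort(sd.CohortSpec(n_positive=1, imbalance_ratio=1, seed=1))
        fm.write_combinations(pos, path)
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        table.loc[0, "rvis_a"] = "abc"
        table.to_csv(path, sep="\t", index=False)
        with pytest.raises(fm.CombinationFormatError, match="abc"):
            fm.read_combinations(path)
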