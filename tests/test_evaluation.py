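"""Metric formulas, curves, LOGO folds and confidence-zone calibration."""

import math

import numpy as np
import pytest

from bilocus import balanced_forest as bf
from bilocus import evaluation as ev
from bilocus import synthetic_data as sd
from bilocus.evaluation import ConfusionMatrix


def sweep_average_precision(y, p):
    """Brute-force threshold sweep oracle for average precision."""
    y, p = np.asarray(y), np.asarray(p)
    n_pos = y.sum()
    area, r_prev = 0.0, 0.0
    for t in sorted(set(p), reverse=True):
        pred = p >= t
        tp = int((pred & (y == 1)).sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        area += (recall - r_prev) * precision
        r_prev = recall
    return area


class TestClassReport:
    def test_hand_arithmetic_case(self):
        rep = ev.class_report(ConfusionMatrix(tp=9, fn=1, fp=5, tn=95))
        assert rep.positive.recall == pytest.approx(0.9)
        assert rep.positive.specificity == pytest.approx(0.95)
        assert rep.positive.geometric_mean == pytest.approx(math.sqrt(0.855))

    def test_perfect_classifier_scores_one(self):
        rep = ev.class_report(ConfusionMatrix(tp=10, fn=0, fp=0, tn=100))
        for m in (rep.positive, rep.negative, rep.weighted):
            assert m.precision == m.recall == m.f1 == 1.0
            assert m.geometric_mean == pytest.approx(1.0)

    def test_zero_division_convention(self):
        rep = ev.class_report(ConfusionMatrix(tp=0, fn=5, fp=0, tn=50))
        assert rep.positive.precision == 0.0
        assert rep.positive.f1 == 0.0

    def test_matches_scalar_arithmetic_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            tp, fn, fp, tn = rng.integers(0, 500, 4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            rep = ev.class_report(ConfusionMatrix(int(tp), int(fn), int(fp), int(tn)))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn)
            spe = tn / (tn + fp)
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert rep.positive.precision == pytest.approx(prec, abs=1e-12)
            assert rep.positive.recall == pytest.approx(rec, abs=1e-12)
            assert rep.positive.specificity == pytest.approx(spe, abs=1e-12)
            assert rep.positive.f1 == pytest.approx(f1, abs=1e-12)
            assert rep.positive.geometric_mean == pytest.approx(
                math.sqrt(rec * spe), abs=1e-12)

    def test_weighted_aggregate_is_convex_combination(self):
        rep = ev.class_report(ConfusionMatrix(tp=40, fn=10, fp=30, tn=920))
        for attr in ("precision", "recall", "f1"):
            lo = min(getattr(rep.positive, attr), getattr(rep.negative, attr))
            hi = max(getattr(rep.positive, attr), getattr(rep.negative, attr))
            assert lo - 1e-12 <= getattr(rep.weighted, attr) <= hi + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fn=0, fp=0, tn=1)


class TestCurves:
    def test_perfect_ranking(self):
        y = [0, 0, 1, 1]
        p = [0.1, 0.2, 0.8, 0.9]
        assert ev.average_precision(y, p) == 1.0
        assert ev.roc_pr_curves(y, p).roc_auc == 1.0

    def test_reversed_scores_invert_roc(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 100)
        y[:5], y[-5:] = 1, 0
        p = rng.random(100)
        auc = ev.roc_pr_curves(y, p).roc_auc
        assert ev.roc_pr_curves(y, 1 - p).roc_auc == pytest.approx(1 - auc)

    def test_random_scores_near_half_auc(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 4000)
        p = rng.random(4000)
        assert 0.45 <= ev.roc_pr_curves(y, p).roc_auc <= 0.55

    def test_permuted_probabilities_ap_near_prevalence(self):
        rng = np.random.default_rng(5)
        y = (rng.random(5000) < 0.2).astype(int)
        p = rng.random(5000)
        assert ev.average_precision(y, p) == pytest.approx(0.2, abs=0.04)

    def test_four_point_toy_matches_sweep(self):
        y = [1, 0, 1, 0]
        p = [0.9, 0.8, 0.6, 0.2]
        assert ev.average_precision(y, p) == pytest.approx(
            sweep_average_precision(y, p), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.average_precision([1, 1], [0.2, 0.4])


class TestLogoFolds:
    def test_shared_pair_instances_stay_together(self, small_cohort):
        pos, neg = small_cohort
        combos = pos + neg
        folds = ev.logo_folds(combos)
        keys = [c.pair_key for c in combos]
        assert len(folds) == len(set(keys))
        for train, test in folds:
            train_keys = {keys[i] for i in train}
            test_keys = {keys[i] for i in test}
            assert len(test_keys) == 1
            assert not (train_keys & test_keys)

    def test_folds_partition_all_instances(self, small_cohort):
        pos, neg = small_cohort
        combos = pos + neg
        folds = ev.logo_folds(combos)
        tested = np.concatenate([test for _, test in folds])
        assert sorted(tested) == list(range(len(combos)))

    def test_all_distinct_pairs_degenerates_to_loo(self):
        pos, _ = sd.gen_cohort(sd.CohortSpec(n_positive=12, imbalance_ratio=1,
                                             n_gene_pairs=500, seed=2))
        keys = {c.pair_key for c in pos}
        folds = ev.logo_folds(pos)
        assert len(folds) == len(keys)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ev.logo_folds([])


class TestRunLogo:
    def test_every_instance_predicted_once(self, small_cohort):
        pos, neg = small_cohort
        result = ev.run_logo_cv(pos + neg, bf.ForestConfig(n_trees=15, seed=3))
        assert not np.isnan(result.probabilities).any()
        assert len(result.probabilities) == len(pos) + len(neg)
        assert result.curves.roc_auc > 0.5  # separable by construction


class TestZones:
    def test_order_statistic_example(self):
        p = np.arange(1, 1001) / 1000.0
        zones = ev.calibrate_zones(p, {"99%": 0.01}, floor=0.0)
        assert zones.thresholds["99%"] == pytest.approx(0.991)
        assert np.mean(p >= zones.thresholds["99%"]) <= 0.01

    def test_all_zero_probabilities(self):
        zones = ev.calibrate_zones(np.zeros(100), {"99%": 0.01}, floor=0.0)
        assert zones.thresholds["99%"] > 0.0

    def test_density_one_gives_zero_threshold(self):
        zones = ev.calibrate_zones(np.linspace(0, 1, 50), {"any": 1.0}, floor=0.0)
        assert zones.thresholds["any"] == 0.0

    def test_density_bound_holds_on_random_sets(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.beta(0.5, 5, size=2000)
            zones = ev.calibrate_zones(p)
            for label, density in (("99%", 0.01), ("99.9%", 0.001)):
                t = zones.thresholds[label]
                assert np.mean(p >= t) <= density

    def test_thresholds_monotone_in_strictness(self):
        rng = np.random.default_rng(7)
        zones = ev.calibrate_zones(rng.random(5000))
        assert 0.5 <= zones.thresholds["99%"] <= zones.thresholds["99.9%"] <= 1.0

    def test_small_calibration_set_warns(self):
        with pytest.warns(UserWarning, match="small"):
            ev.calibrate_zones(np.random.default_rng(1).random(50))

    def test_empty_calibration_set_rejected(self):
        with pytest.raises(ValueError):
            ev.calibrate_zones([])


class TestAssignZone:
    def test_published_thresholds(self):
        assert ev.assign_zone(0.9) == "99.9%"
        assert ev.assign_zone(0.8) == "99%"
        assert ev.assign_zone(0.6) == "disease_causing"
        assert ev.assign_zone(0.4) == "neutral"

    def test_boundaries_are_inclusive(self):
        assert ev.assign_zone(0.743) == "99%"
        assert ev.assign_zone(0.891) == "99.9%"
        assert ev.assign_zone(0.5) == "disease_causing"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ev.assign_zone(1.2)
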