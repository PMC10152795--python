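"""Imbalance-aware evaluation: per-class metrics, LOGO cross-validation,
ROC/PR curves and confidence-zone calibration.

With a 1:500 positive:neutral ratio, accuracy is meaningless; the
metrics here are computed per class (precision, recall, specificity,
F1, geometric mean of the two recalls) and aggregated weighted by class
support.  Cross-validation is leave-one-group-out with gene pairs as
the groups, so no gene pair ever appears on both sides of a split, and
metrics are computed once on the pooled out-of-fold predictions.
Confidence zones translate prediction-probability thresholds into an
expected false-positive density among neutral inputs (1% and 0.1% by
default), calibrated from the empirical probability distribution of a
held-out neutral set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn import metrics as skmetrics

from . import balanced_forest
from .balanced_forest import ForestConfig
from .feature_model import (
    BilocusCombination,
    FeatureLayout,
    PRODUCTION15_LAYOUT,
    combinations_frame,
    fit_imputer,
)

logger = logging.getLogger(__name__)

#: Zone thresholds published with the reference model (classification /
#: 99% zone / 99.9% zone).  They derive from the original 10,000-strong
#: neutral calibration set and are not reproducible from synthetic data;
#: use calibrate_zones for models trained here.
PUBLISHED_ZONES: "ConfidenceZones"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )


def _div(num: float, den: float) -> float:
    return num / den if den else 0.0  # 0/0 -> 0 convention


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    specificity: float
    f1: float
    geometric_mean: float
    support: int


@dataclass(frozen=True)
class ClassReport:
    positive: ClassMetrics
    negative: ClassMetrics
    weighted: ClassMetrics
    confusion: ConfusionMatrix

    def as_dict(self) -> dict:
        out = {}
        for name, cm in (("disease_causing", self.positive),
                         ("neutral", self.negative),
                         ("weighted", self.weighted)):
            out[name] = {
                "precision": cm.precision, "recall": cm.recall,
                "specificity": cm.specificity, "f1": cm.f1,
                "geometric_mean": cm.geometric_mean, "support": cm.support,
            }
        out["confusion"] = {
            "tp": self.confusion.tp, "fn": self.confusion.fn,
            "fp": self.confusion.fp, "tn": self.confusion.tn,
        }
        return out


def class_report(cm: ConfusionMatrix) -> ClassReport:
    """Per-class precision/recall/specificity/F1/geometric-mean plus the
    support-weighted aggregate.

    For the negative class the roles are swapped: its "true positives"
    are the true negatives.  The geometric mean sqrt(recall- * recall+)
    is a property of the classifier, identical for both classes.
    """
    recall_pos = _div(cm.tp, cm.tp + cm.fn)
    recall_neg = _div(cm.tn, cm.tn + cm.fp)
    geo = float(np.sqrt(recall_neg * recall_pos))

    def build(tp, fn, fp, tn, recall, specificity, support) -> ClassMetrics:
        precision = _div(tp, tp + fp)
        f1 = _div(2 * precision * recall, precision + recall)
        return ClassMetrics(precision, recall, specificity, f1, geo, support)

    pos = build(cm.tp, cm.fn, cm.fp, cm.tn, recall_pos, recall_neg, cm.tp + cm.fn)
    neg = build(cm.tn, cm.fp, cm.fn, cm.tp, recall_neg, recall_pos, cm.tn + cm.fp)

    total = pos.support + neg.support
    if total == 0:
        raise ValueError("empty confusion matrix")

    def wavg(attr: str) -> float:
        return (getattr(pos, attr) * pos.support + getattr(neg, attr) * neg.support) / total

    weighted = ClassMetrics(
        *(wavg(a) for a in ("precision", "recall", "specificity", "f1", "geometric_mean")),
        support=total,
    )
    return ClassReport(positive=pos, negative=neg, weighted=weighted, confusion=cm)


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def average_precision(labels, probabilities) -> float:
    """Average precision: step-wise area under the PR curve,
    sum_i (R_i - R_{i-1}) P_i over descending score thresholds."""
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    return float(skmetrics.average_precision_score(labels, np.asarray(probabilities, dtype=float)))


@dataclass(frozen=True)
class Curves:
    fpr: np.ndarray
    tpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    roc_auc: float
    average_precision: float


def roc_pr_curves(labels, probabilities) -> Curves:
    labels = np.asarray(labels).astype(int)
    probabilities = np.asarray(probabilities, dtype=float)
    _check_two_classes(labels)
    fpr, tpr, _ = skmetrics.roc_curve(labels, probabilities)
    precision, recall, _ = skmetrics.precision_recall_curve(labels, probabilities)
    return Curves(
        fpr=fpr, tpr=tpr, precision=precision, recall=recall,
        roc_auc=float(skmetrics.auc(fpr, tpr)),
        average_precision=average_precision(labels, probabilities),
    )


# ---------------------------------------------------------------------------
# gene-pair-stratified cross-validation
# ---------------------------------------------------------------------------


def logo_folds(
    combinations: Sequence[BilocusCombination],
) -> list[tuple[np.ndarray, np.ndarray]]:
    """One fold per distinct gene pair: test = all instances of the pair,
    train = everything else.  Folds ordered by sorted pair key."""
    if not combinations:
        raise ValueError("no combinations given")
    groups: dict[tuple[str, str], list[int]] = {}
    for i, c in enumerate(combinations):
        groups.setdefault(c.pair_key, []).append(i)
    all_idx = np.arange(len(combinations))
    folds = []
    for key in sorted(groups):
        test = np.array(groups[key])
        train = np.setdiff1d(all_idx, test)
        folds.append((train, test))
    return folds


@dataclass
class LogoResult:
    probabilities: np.ndarray  # pooled out-of-fold probabilities, input order
    labels: np.ndarray
    report: ClassReport
    curves: Curves
    skipped_folds: list[tuple[str, str]] = field(default_factory=list)


def run_logo_cv(
    combinations: Sequence[BilocusCombination],
    config: ForestConfig = ForestConfig(),
    layout: FeatureLayout = PRODUCTION15_LAYOUT,
    threshold: float = 0.5,
) -> LogoResult:
    """Gene-pair LOGO CV: per fold, fit the imputer and forest on the
    training side only, predict the held-out pair, then score the pooled
    predictions once."""
    labels = np.array([1 if c.label == "disease_causing" else 0 for c in combinations])
    _check_two_classes(labels)
    frame = combinations_frame(combinations, layout)
    folds = logo_folds(combinations)

    prob = np.full(len(combinations), np.nan)
    skipped: list[tuple[str, str]] = []
    for fold_i, (train_idx, test_idx) in enumerate(folds):
        y_train = labels[train_idx]
        if len(np.unique(y_train)) < 2:
            key = combinations[test_idx[0]].pair_key
            logger.warning("skipping fold %s: training side single-class", key)
            skipped.append(key)
            continue
        imputer = fit_imputer(
            frame.iloc[train_idx[y_train == 1]], frame.iloc[train_idx[y_train == 0]],
            layout, strict=False,
        )
        X_train = imputer.transform(frame.iloc[train_idx]).to_numpy(dtype=float)
        fold_config = ForestConfig(
            n_trees=config.n_trees, max_depth=config.max_depth,
            seed=config.seed + fold_i, structure=config.structure,
            ensemble_size=config.ensemble_size, imbalance_ratio=config.imbalance_ratio,
        )
        model = balanced_forest.train_comparison_structure(
            X_train[y_train == 1], X_train[y_train == 0], fold_config, layout, imputer
        )
        X_test = imputer.transform(frame.iloc[test_idx]).to_numpy(dtype=float)
        prob[test_idx] = model.predict_proba(X_test)

    scored = ~np.isnan(prob)
    y, p = labels[scored], prob[scored]
    report = class_report(ConfusionMatrix.from_predictions(y, p >= threshold))
    return LogoResult(
        probabilities=prob, labels=labels, report=report,
        curves=roc_pr_curves(y, p), skipped_folds=skipped,
    )


# ---------------------------------------------------------------------------
# confidence zones
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfidenceZones:
    """Probability thresholds: classification at 0.5, then zones whose
    expected false-positive density among neutral inputs is bounded."""

    thresholds: Mapping[str, float]  # zone label -> threshold
    classification_threshold: float = 0.5

    def __post_init__(self):
        for t in self.thresholds.values():
            if not 0.0 <= t <= 1.0:
                raise ValueError("zone thresholds must lie in [0, 1]")

    def ordered_labels(self) -> list[str]:
        return sorted(self.thresholds, key=lambda k: self.thresholds[k])


PUBLISHED_ZONES = ConfidenceZones(thresholds={"99%": 0.743, "99.9%": 0.891})


def calibrate_zones(
    neutral_probabilities,
    fp_densities: Mapping[str, float] = {"99%": 0.01, "99.9%": 0.001},
    floor: float = 0.5,
) -> ConfidenceZones:
    """Thresholds from the empirical neutral probability distribution.

    For each target density d the threshold is the smallest probability
    t such that the fraction of calibration probabilities >= t is <= d
    (order statistics, no smoothing); with the >= classification rule
    this bounds the calibration-set FP density by construction.  Since a
    zone below the classification threshold is meaningless, thresholds
    are floored at 0.5 by default (``floor=0.0`` gives the raw order
    statistic).
    """
    p = np.sort(np.asarray(neutral_probabilities, dtype=float))[::-1]
    n = len(p)
    if n == 0:
        raise ValueError("empty calibration set")
    if n < 1 / min(fp_densities.values()):
        warnings.warn(
            f"calibration set of {n} points is small for density "
            f"{min(fp_densities.values())}; thresholds will be coarse"
        )
    thresholds = {}
    for label, density in fp_densities.items():
        allowed = int(np.floor(density * n))
        if allowed >= n:
            t = 0.0
        else:
            # candidate thresholds: observed values (fraction >= p[k] is
            # at least k+1) — take the smallest observed t that satisfies
            # the bound, else step just above the maximum
            t = None
            for k in range(min(allowed, n - 1), -1, -1):
                cand = p[k]
                if np.sum(p >= cand) <= allowed:
                    t = float(cand)
                    break
            if t is None:
                t = float(np.nextafter(p[0], np.inf))
        thresholds[label] = max(t, floor)
    # enforce monotone ordering by target strictness
    ordered = sorted(thresholds, key=lambda k: -fp_densities[k])
    last = floor
    for label in ordered:
        thresholds[label] = max(thresholds[label], last)
        last = thresholds[label]
    return ConfidenceZones(thresholds=thresholds)


def assign_zone(prob: float, zones: ConfidenceZones = PUBLISHED_ZONES) -> str:
    """Highest zone whose threshold <= prob; below 0.5 -> neutral."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError("probability must be in [0, 1]")
    best = None
    for label in zones.ordered_labels():
        if prob >= zones.thresholds[label]:
            best = label
    if best is not None:
        return best
    return "disease_causing" if prob >= zones.classification_threshold else "neutral"
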