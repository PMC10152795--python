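"""Model interpretation: global Gini importance and local prediction
decomposition.

Global: for each tree, every internal node's weighted Gini impurity
decrease (node sample fraction times parent impurity minus the weighted
child impurities) is credited to its split feature and the per-tree
totals are normalized to sum to 1; the forest view is the distribution
of these per-tree importances, boxplot-ready per feature.

Local: each tree's prediction is decomposed along the decision path into
a fixed bias (the root's class-1 fraction) plus one contribution per
feature — the change in class-1 fraction at every node whose split that
feature controls.  The identity bias + sum(contributions) = predicted
probability holds exactly per tree, and taking means preserves it for
the forest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .balanced_forest import BalancedForestModel, _check_matrix


@dataclass(frozen=True)
class ImportanceReport:
    feature_names: tuple[str, ...]
    per_tree: np.ndarray  # shape (n_trees, n_features); rows sum to 1 (or 0)

    @property
    def forest_mean(self) -> np.ndarray:
        return self.per_tree.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_tree, columns=list(self.feature_names))


def _tree_importances(tree: DecisionTreeClassifier, n_features: int) -> np.ndarray:
    """Normalized weighted-impurity-decrease importances for one tree."""
    t = tree.tree_
    imp = np.zeros(n_features)
    total = t.weighted_n_node_samples[0]
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        w = t.weighted_n_node_samples
        decrease = (
            w[node] * t.impurity[node]
            - w[left] * t.impurity[left]
            - w[right] * t.impurity[right]
        ) / total
        imp[t.feature[node]] += decrease
    s = imp.sum()
    return imp / s if s > 0 else imp


def gini_importance(model: BalancedForestModel) -> ImportanceReport:
    if not model.trees:
        raise ValueError("untrained model")
    names = model.layout.features
    per_tree = np.vstack([_tree_importances(t, len(names)) for t in model.trees])
    return ImportanceReport(feature_names=names, per_tree=per_tree)


@dataclass(frozen=True)
class LocalContribution:
    feature_names: tuple[str, ...]
    bias: float
    contributions: np.ndarray

    @property
    def prediction(self) -> float:
        return float(self.bias + self.contributions.sum())


def _class1_fraction(tree: DecisionTreeClassifier, node: int) -> float:
    counts = tree.tree_.value[node][0]
    # tree_.value rows may be normalized depending on sklearn version;
    # renormalizing is correct either way
    frac = counts / counts.sum()
    idx = list(tree.classes_).index(1)
    return float(frac[idx])


def _tree_contributions(
    tree: DecisionTreeClassifier, x: np.ndarray, n_features: int
) -> tuple[float, np.ndarray]:
    t = tree.tree_
    bias = _class1_fraction(tree, 0)
    contrib = np.zeros(n_features)
    node = 0
    while t.children_left[node] != -1:
        feat = t.feature[node]
        child = (
            t.children_left[node]
            if x[feat] <= t.threshold[node]
            else t.children_right[node]
        )
        contrib[feat] += _class1_fraction(tree, child) - _class1_fraction(tree, node)
        node = child
    return bias, contrib


def local_contributions(model: BalancedForestModel, vector: np.ndarray) -> LocalContribution:
    """Forest-level bias and per-feature contributions for one sample."""
    x = _check_matrix(vector, len(model.layout))[0]
    biases, contribs = [], []
    for tree in model.trees:
        b, c = _tree_contributions(tree, x, len(model.layout))
        biases.append(b)
        contribs.append(c)
    return LocalContribution(
        feature_names=model.layout.features,
        bias=float(np.mean(biases)),
        contributions=np.mean(contribs, axis=0),
    )


def contribution_report(
    model: BalancedForestModel,
    vectors: np.ndarray,
    labels: Sequence[str] | Sequence[int],
    class_label,
) -> pd.DataFrame:
    """Per-feature contribution distribution over one class of a cohort.

    Returns a DataFrame (instances x features) of local contributions
    for the instances carrying ``class_label`` — boxplot-ready.
    """
    labels = np.asarray(labels)
    mask = labels == class_label
    if not mask.any():
        raise ValueError(f"no instances with label {class_label!r}")
    X = _check_matrix(vectors, len(model.layout))[mask]
    rows = [local_contributions(model, x).contributions for x in X]
    return pd.DataFrame(rows, columns=list(model.layout.features))
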