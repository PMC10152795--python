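"""Balanced random forest for pathogenicity probability prediction.

Disease-causing bilocus combinations are rare (here, a 1:500 positive to
neutral ratio), so an ordinary forest bootstrap would be swamped by the
majority class.  The balanced forest instead draws, for every tree, a
bootstrap sample of the minority class and an equally sized
with-replacement sample of the majority class — each tree trains on a
1:1 multiset while the forest as a whole sees all majority data.  Tree
fitting itself uses CART with Gini splitting, a depth cap (default 10)
and sqrt(d) candidate features per split; the forest probability is the
unweighted mean over trees of the leaf class-1 fraction.

Two comparison structures are provided for model-structure experiments:
a plain forest trained on a single 1:1 down-sample of the majority
class, and an ensemble of independently subsampled forests whose
probabilities are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .feature_model import FeatureLayout, ImputationModel, LAYOUTS, PRODUCTION15_LAYOUT

ARTIFACT_VERSION = "bilocus-model-1"


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 400
    max_depth: int = 10
    seed: int = 0
    structure: str = "balanced_forest"  # | plain_forest | forest_ensemble
    ensemble_size: int = 10
    imbalance_ratio: Optional[int] = 500  # documentation only; data carry it

    def __post_init__(self):
        if self.n_trees < 1 or self.max_depth < 1:
            raise ValueError("n_trees and max_depth must be positive")
        if self.structure not in ("balanced_forest", "plain_forest", "forest_ensemble"):
            raise ValueError(f"unknown structure {self.structure!r}")


def balanced_bootstrap(
    n_min: int, n_maj: int, seed: int | np.random.SeedSequence
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tree sample: n_min minority draws + n_min majority draws,
    both with replacement.  Deterministic per seed."""
    if n_min < 1 or n_maj < 1:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)
    minority = rng.integers(0, n_min, size=n_min)
    majority = rng.integers(0, n_maj, size=n_min)
    return minority, majority


@dataclass
class BalancedForestModel:
    trees: list[DecisionTreeClassifier]
    layout: FeatureLayout
    config: ForestConfig
    imputer: Optional[ImputationModel] = None
    #: per-tree (n_minority_drawn, n_majority_drawn) — asserts the 1:1 invariant
    sample_log: list[tuple[int, int]] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean over trees of the class-1 (disease-causing) leaf fraction."""
        X = _check_matrix(X, len(self.layout))
        acc = np.zeros(X.shape[0])
        for tree in self.trees:
            acc += _tree_proba(tree, X)
        return acc / len(self.trees)


def _check_matrix(X: np.ndarray, width: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != width:
        raise ValueError(f"feature matrix has {X.shape[1]} columns, layout expects {width}")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values; impute first")
    return X


def _tree_proba(tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
    proba = tree.predict_proba(X)
    idx = list(tree.classes_).index(1)
    return proba[:, idx]


def train(
    pos: np.ndarray,
    neg: np.ndarray,
    config: ForestConfig = ForestConfig(),
    layout: FeatureLayout = PRODUCTION15_LAYOUT,
    imputer: Optional[ImputationModel] = None,
) -> BalancedForestModel:
    """Fit the balanced forest from positive- and negative-class matrices.

    A master seed spawns one child seed per tree, so results do not
    depend on execution order and a fixed seed reproduces the model
    bit-identically.
    """
    pos = _check_matrix(pos, len(layout))
    neg = _check_matrix(neg, len(layout))
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    # the minority class defines the per-tree sample size
    if len(pos) <= len(neg):
        minority, majority, min_label, maj_label = pos, neg, 1, 0
    else:
        minority, majority, min_label, maj_label = neg, pos, 0, 1

    master = np.random.SeedSequence(config.seed)
    trees: list[DecisionTreeClassifier] = []
    sample_log: list[tuple[int, int]] = []
    for tree_seq in master.spawn(config.n_trees):
        boot_seq, fit_seq = tree_seq.spawn(2)
        idx_min, idx_maj = balanced_bootstrap(len(minority), len(majority), boot_seq)
        X = np.vstack([minority[idx_min], majority[idx_maj]])
        y = np.array([min_label] * len(idx_min) + [maj_label] * len(idx_maj))
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_depth=config.max_depth,
            max_features="sqrt",
            random_state=int(fit_seq.generate_state(1)[0] % (2**31)),
        )
        tree.fit(X, y)
        trees.append(tree)
        sample_log.append((len(idx_min), len(idx_maj)))
    return BalancedForestModel(
        trees=trees, layout=layout, config=config, imputer=imputer, sample_log=sample_log
    )


def predict_proba(model, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)


def classify(prob, threshold: float = 0.5):
    """Disease-causing iff probability >= threshold (boundary positive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    prob = np.asarray(prob, dtype=float)
    labels = np.where(prob >= threshold, "disease_causing", "neutral")
    return labels if labels.ndim else labels.item()


# ---------------------------------------------------------------------------
# comparison model structures
# ---------------------------------------------------------------------------


@dataclass
class PlainForestModel:
    """Ordinary forest trained once on a 1:1 down-sample of the majority."""

    forest: RandomForestClassifier
    layout: FeatureLayout
    config: ForestConfig
    imputer: Optional[ImputationModel] = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = _check_matrix(X, len(self.layout))
        idx = list(self.forest.classes_).index(1)
        return self.forest.predict_proba(X)[:, idx]


@dataclass
class ForestEnsembleModel:
    """k forests, each on its own balanced subsample; probabilities averaged."""

    forests: list[RandomForestClassifier]
    layout: FeatureLayout
    config: ForestConfig
    imputer: Optional[ImputationModel] = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = _check_matrix(X, len(self.layout))
        acc = np.zeros(X.shape[0])
        for f in self.forests:
            idx = list(f.classes_).index(1)
            acc += f.predict_proba(X)[:, idx]
        return acc / len(self.forests)


def train_comparison_structure(
    pos: np.ndarray,
    neg: np.ndarray,
    config: ForestConfig,
    layout: FeatureLayout = PRODUCTION15_LAYOUT,
    imputer: Optional[ImputationModel] = None,
):
    """Train one of the comparison structures (or delegate to the
    balanced forest) under the shared predict_proba contract."""
    if config.structure == "balanced_forest":
        return train(pos, neg, config, layout, imputer)
    pos = _check_matrix(pos, len(layout))
    neg = _check_matrix(neg, len(layout))
    master = np.random.SeedSequence(config.seed)

    def fit_forest(neg_sample: np.ndarray, seq: np.random.SeedSequence) -> RandomForestClassifier:
        X = np.vstack([pos, neg_sample])
        y = np.array([1] * len(pos) + [0] * len(neg_sample))
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            criterion="gini",
            max_features="sqrt",
            random_state=int(seq.generate_state(1)[0] % (2**31)),
        )
        forest.fit(X, y)
        return forest

    if config.structure == "plain_forest":
        sub_seq, fit_seq = master.spawn(2)
        rng = np.random.default_rng(sub_seq)
        take = rng.choice(len(neg), size=min(len(pos), len(neg)), replace=False)
        return PlainForestModel(fit_forest(neg[take], fit_seq), layout, config, imputer)

    forests = []
    for seq in master.spawn(config.ensemble_size):
        sub_seq, fit_seq = seq.spawn(2)
        rng = np.random.default_rng(sub_seq)
        take = rng.choice(len(neg), size=min(len(pos), len(neg)), replace=False)
        forests.append(fit_forest(neg[take], fit_seq))
    return ForestEnsembleModel(forests, layout, config, imputer)


# ---------------------------------------------------------------------------
# model artifact
# ---------------------------------------------------------------------------


def save_model(model: BalancedForestModel, path) -> None:
    payload = {
        "version": ARTIFACT_VERSION,
        "layout_name": model.layout.name,
        "config": asdict(model.config),
        "imputer": model.imputer,
        "trees": model.trees,
        "sample_log": model.sample_log,
    }
    joblib.dump(payload, path)


def load_model(path) -> BalancedForestModel:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("version") != ARTIFACT_VERSION:
        raise ValueError(
            f"unsupported model artifact (expected version {ARTIFACT_VERSION!r})"
        )
    return BalancedForestModel(
        trees=payload["trees"],
        layout=LAYOUTS[payload["layout_name"]],
        config=ForestConfig(**payload["config"]),
        imputer=payload["imputer"],
        sample_log=payload["sample_log"],
    )
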