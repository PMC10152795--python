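"""Wrapper feature selection by memoized random-restart local search.

The search space is every subset of the 20-feature layout, encoded as a
bitmask.  The objective is the mean positive-class F1 of a k-fold
cross-validated random forest trained on a balanced (equal class count)
candidate set restricted to the subset's features.  Each restart begins
at a uniformly random subset; every step draws a fixed number of random
single-bit-flip neighbors, moves to the best one only on strict
improvement, and the restart stops once the incumbent has survived a
fixed number of consecutive non-improving steps.  Objective values are
memoized by bitmask so re-encountered subsets cost nothing.  The
reference configuration (10,000 restarts, 10 neighbors/step, 100
stability steps, 5-fold CV of a 100-tree forest on a 301:301 sample)
is the default; tests and examples use scaled-down profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class SearchConfig:
    n_restarts: int = 10_000
    neighbors_per_step: int = 10
    stability_steps: int = 100
    cv_folds: int = 5
    forest_trees: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("n_restarts", "neighbors_per_step", "stability_steps",
                     "cv_folds", "forest_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class MemoCache:
    values: dict[int, float] = field(default_factory=dict)
    hits: int = 0
    misses: int = 0

    def get(self, mask: int) -> Optional[float]:
        if mask in self.values:
            self.hits += 1
            return self.values[mask]
        return None

    def put(self, mask: int, value: float) -> None:
        self.misses += 1
        self.values[mask] = value


def mask_to_indices(mask: int, n_features: int) -> np.ndarray:
    return np.array([i for i in range(n_features) if mask >> i & 1], dtype=int)


def indices_to_mask(indices) -> int:
    mask = 0
    for i in indices:
        mask |= 1 << int(i)
    return mask


def subset_objective(
    mask: int,
    X: np.ndarray,
    y: np.ndarray,
    config: SearchConfig,
    cache: Optional[MemoCache] = None,
) -> float:
    """Mean positive-class F1 of a seeded k-fold CV forest on the masked
    features; the empty subset scores a defined 0."""
    if cache is not None:
        cached = cache.get(mask)
        if cached is not None:
            return cached
    if mask == 0:
        value = 0.0
    else:
        cols = mask_to_indices(mask, X.shape[1])
        Xm = X[:, cols]
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
        scores = []
        for train_idx, test_idx in skf.split(Xm, y):
            forest = RandomForestClassifier(
                n_estimators=config.forest_trees, random_state=config.seed
            )
            forest.fit(Xm[train_idx], y[train_idx])
            scores.append(
                f1_score(y[test_idx], forest.predict(Xm[test_idx]), zero_division=0)
            )
        value = float(np.mean(scores))
    if cache is not None:
        cache.put(mask, value)
    return value


def random_neighbor(mask: int, rng: np.random.Generator, n_features: int) -> int:
    """Flip one uniformly chosen feature bit (Hamming distance 1)."""
    return mask ^ (1 << int(rng.integers(n_features)))


@dataclass
class SearchResult:
    best_mask: int
    best_objective: float
    traces: list[list[float]]  # incumbent objective per step, per restart
    cache: MemoCache


def _tie_break_key(mask: int, n_features: int) -> tuple[int, int]:
    return (bin(mask).count("1"), mask)


def local_search(
    X: np.ndarray,
    y: np.ndarray,
    config: SearchConfig,
    n_features: Optional[int] = None,
) -> SearchResult:
    """Random-restart stochastic hill climbing over feature subsets.

    Returns the best subset over all restarts; ties resolve toward the
    smaller cardinality, then the lexicographically smaller bitmask.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    d = n_features if n_features is not None else X.shape[1]
    if d < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(config.seed)
    cache = MemoCache()

    best_mask, best_value = 0, -np.inf
    traces: list[list[float]] = []
    full = (1 << d) - 1
    for _ in range(config.n_restarts):
        incumbent = int(rng.integers(0, full + 1))
        inc_value = subset_objective(incumbent, X, y, config, cache)
        trace = [inc_value]
        stagnant = 0
        while stagnant < config.stability_steps:
            cand_best, cand_value = None, -np.inf
            for _ in range(config.neighbors_per_step):
                nb = random_neighbor(incumbent, rng, d)
                v = subset_objective(nb, X, y, config, cache)
                if v > cand_value or (
                    v == cand_value
                    and cand_best is not None
                    and _tie_break_key(nb, d) < _tie_break_key(cand_best, d)
                ):
                    cand_best, cand_value = nb, v
            if cand_value > inc_value:  # strict improvement only
                incumbent, inc_value = cand_best, cand_value
                stagnant = 0
            else:
                stagnant += 1
            trace.append(inc_value)
        traces.append(trace)
        if inc_value > best_value or (
            inc_value == best_value
            and _tie_break_key(incumbent, d) < _tie_break_key(best_mask, d)
        ):
            best_mask, best_value = incumbent, inc_value
    return SearchResult(best_mask=best_mask, best_objective=best_value,
                        traces=traces, cache=cache)
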