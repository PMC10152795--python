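import numpy as np
import pytest

from bilocus import balanced_forest as bf
from bilocus import feature_model as fm
from bilocus import synthetic_data as sd


@pytest.fixture(scope="session")
def separable_matrices():
    """Well-separated positive/negative full20 matrices (vector-level view)."""
    spec = sd.CohortSpec(n_positive=40, imbalance_ratio=25, seed=11)
    return sd.gen_feature_matrices(spec)


@pytest.fixture(scope="session")
def small_model(separable_matrices):
    """A small balanced forest trained on the separable matrices."""
    Xp, Xn = separable_matrices
    config = bf.ForestConfig(n_trees=30, max_depth=10, seed=5)
    return bf.train(Xp, Xn, config, layout=fm.FULL20_LAYOUT)


@pytest.fixture(scope="session")
def small_cohort():
    """Combination-level cohort with gene-pair structure for CV tests."""
    spec = sd.CohortSpec(n_positive=15, imbalance_ratio=10, n_gene_pairs=30, seed=21)
    return sd.gen_cohort(spec)
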