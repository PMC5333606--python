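import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from parenclitic import Cohort, Relation, SyntheticConfig, generate_cohort


@pytest.fixture
def small_linear_config():
    """4 numeric features, one exact-by-construction linear relation."""
    return SyntheticConfig(
        n_controls=300, n_cases=0, n_numeric=4, n_binary=0,
        relation_pairs=(Relation("num_01", "num_03", 0.5, 1.2, 0.4),),
        seed=42)


@pytest.fixture
def gaussian_cohort():
    """Balanced all-Gaussian cohort with two relations, no class signal."""
    config = SyntheticConfig(
        n_controls=150, n_cases=150, n_numeric=6, n_binary=0,
        relation_pairs=(
            Relation("num_01", "num_02", 0.0, 1.0, 0.5),
            Relation("num_03", "num_05", -0.2, -0.8, 0.7),
        ),
        seed=7)
    return generate_cohort(config)


def make_cohort(X, labels, feature_names=None, label_column="DEATH"):
    """Assemble a Cohort from a plain array + labels."""
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"f{j + 1}" for j in range(X.shape[1])]
    frame = pd.DataFrame(X, columns=feature_names)
    frame.insert(0, label_column, np.asarray(labels, dtype=int))
    frame.index = pd.Index([f"S{i}" for i in range(len(frame))],
                           name="subject_id")
    return Cohort(frame, label_column)


@pytest.fixture
def make_cohort_fixture():
    return make_cohort
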