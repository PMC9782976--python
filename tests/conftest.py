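import numpy as np
import pandas as pd
import pytest

from ekbn.dataset_io import FeatureRole, FeatureTable
from ekbn.synthetic import ScenarioSpec, make_ground_truth, sample_dataset


@pytest.fixture
def toy_table() -> FeatureTable:
    """4 units, 2 binary features, balanced-ish outcome."""
    features = pd.DataFrame({
        "f1": pd.Categorical([0, 1, 0, 1], categories=[0, 1]),
        "f2": pd.Categorical([1, 1, 0, 0], categories=[0, 1]),
    })
    return FeatureTable(
        units=["a", "b", "c", "d"],
        outcome_name="y",
        outcome=np.array([0, 0, 1, 1]),
        features=features,
        roles={"f1": FeatureRole(is_ekf=True), "f2": FeatureRole(phase="during")},
        levels={"f1": [0, 1], "f2": [0, 1]},
    )


@pytest.fixture(scope="session")
def small_truth():
    """Outcome + 4-member blanket (parent, child, two spouses) + shadows + noise."""
    spec = ScenarioSpec(n_units=500, prevalence=0.28, n_mb=4, n_redundant=3,
                        n_noise=8, n_ekf=6, seed=1)
    return make_ground_truth(spec)


@pytest.fixture(scope="session")
def small_sample(small_truth):
    return sample_dataset(small_truth, 5000, seed=2)


def noise_table(n_units: int, n_features: int, n_ekf: int, prevalence: float,
                seed: int) -> FeatureTable:
    """A cohort in which the outcome is independent of every feature."""
    rng = np.random.default_rng(seed)
    feats = {f"x{i:02d}": pd.Categorical(rng.integers(0, 2, n_units), categories=[0, 1])
             for i in range(n_features)}
    n_event = max(2, round(prevalence * n_units))
    outcome = np.zeros(n_units, dtype=np.int8)
    outcome[rng.choice(n_units, n_event, replace=False)] = 1
    roles = {name: FeatureRole(is_ekf=(i < n_ekf))
             for i, name in enumerate(feats)}
    return FeatureTable(
        units=[f"u{i}" for i in range(n_units)],
        outcome_name="y", outcome=outcome,
        features=pd.DataFrame(feats), roles=roles,
        levels={k: [0, 1] for k in feats},
    )
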