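import numpy as np
import pytest

from galambda.datamodel import FeatureTable
from galambda.synthetic import SyntheticSpec, generate_feature_table


@pytest.fixture(scope="session")
def planted_table():
    """n=180, p=300, 10 planted log-odds effects of magnitude 1.5."""
    spec = SyntheticSpec(n_samples=180, n_features=300, n_informative=10, seed=42)
    return generate_feature_table(spec)


@pytest.fixture(scope="session")
def small_table():
    """Small table with 3 strong planted features among 40 (n=120)."""
    spec = SyntheticSpec(
        n_samples=120,
        n_features=40,
        n_informative=3,
        effect_sizes=(2.0, -2.0, 2.0),
        seed=7,
    )
    return generate_feature_table(spec)


@pytest.fixture
def tiny_table():
    rng = np.random.default_rng(0)
    values = rng.standard_normal((12, 4))
    labels = np.array([0, 1] * 6)
    return FeatureTable(
        values,
        tuple(f"f{i}" for i in range(4)),
        labels,
        tuple(f"s{i}" for i in range(12)),
    )
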