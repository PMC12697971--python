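import numpy as np
import pytest

from hmfw import ExpressionDataset, SyntheticSpec, generate_synthetic_omics


@pytest.fixture(scope="session")
def small_synth():
    """60 samples x 200 features, 5 planted informative, 1 redundant copy each."""
    spec = SyntheticSpec(
        n_samples=60,
        n_features=200,
        n_informative=5,
        n_redundant_per_informative=1,
        n_classes=2,
        class_separation=2.0,
        redundancy_rho=0.8,
        seed=42,
    )
    return generate_synthetic_omics(spec)


@pytest.fixture(scope="session")
def tiny_ds():
    """Deterministic 12-sample, 6-feature dataset for exact filter arithmetic."""
    rng = np.random.default_rng(3)
    mat = rng.normal(size=(12, 6))
    labels = np.array([0, 1] * 6)
    mat[:, 0] += labels * 3.0  # feature 0 tracks the label
    return ExpressionDataset(
        mat, labels, [f"g{j}" for j in range(6)], [f"s{i}" for i in range(12)]
    )


@pytest.fixture(scope="session")
def separable_ds():
    """Two classes split by feature 0 with an 8-SD gap; features 1+ are noise."""
    rng = np.random.default_rng(11)
    n = 60
    labels = np.array([0, 1] * (n // 2))
    mat = rng.normal(size=(n, 20))
    mat[:, 0] += labels * 8.0
    return ExpressionDataset(
        mat, labels, [f"g{j}" for j in range(20)], [f"s{i}" for i in range(n)]
    )
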