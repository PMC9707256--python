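import numpy as np
import pandas as pd
import pytest

from coessnet import FitnessMatrix, SyntheticSpec, generate


@pytest.fixture
def small_matrix() -> FitnessMatrix:
    """3 genes x 4 samples with distinct, hand-checkable profiles."""
    return FitnessMatrix(pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [2.0, 4.0, 6.0, 8.0],
         [4.0, 3.0, 2.0, 1.0]],
        index=["GA", "GB", "GC"],
        columns=["ACH-000001", "ACH-000002", "ACH-000003", "ACH-000004"]))


@pytest.fixture
def random_matrix() -> FitnessMatrix:
    rng = np.random.default_rng(7)
    return FitnessMatrix(pd.DataFrame(
        rng.normal(size=(50, 8)),
        index=[f"G{i:03d}" for i in range(50)],
        columns=[f"S{j}" for j in range(8)]))


@pytest.fixture
def default_synthetic():
    """Desk-scale synthetic matrix with planted modules/blocks/trios."""
    return generate(SyntheticSpec(seed=11))


def random_spd(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.normal(size=(n, n))
    return a @ a.T / n + 0.1 * np.eye(n)
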