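import numpy as np
import pytest

from hidimsel import ExpressionDataset


def toy_dataset(
    n_genes: int = 6,
    n_per_class: int = 10,
    n_informative: int = 2,
    effect: float = 2.0,
    seed: int = 0,
) -> ExpressionDataset:
    """Small two-class dataset with the first genes carrying a mean shift."""
    rng = np.random.default_rng(seed)
    values = rng.normal(10.0, 1.0, size=(n_genes, 2 * n_per_class))
    values[:n_informative, n_per_class:] += effect
    return ExpressionDataset(
        [f"g{i + 1}" for i in range(n_genes)],
        [f"s{i + 1}" for i in range(2 * n_per_class)],
        values,
        np.array([0] * n_per_class + [1] * n_per_class),
    )


@pytest.fixture
def small_ds() -> ExpressionDataset:
    return toy_dataset()


@pytest.fixture
def separable_ds() -> ExpressionDataset:
    """20+20 samples; gene g1 is 0 in class 0 and 1 in class 1."""
    rng = np.random.default_rng(42)
    values = rng.normal(5.0, 1.0, size=(3, 40))
    values[0, :20] = 0.0
    values[0, 20:] = 1.0
    return ExpressionDataset(
        ["g1", "g2", "g3"],
        [f"s{i}" for i in range(40)],
        values,
        np.array([0] * 20 + [1] * 20),
    )
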