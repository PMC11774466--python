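import numpy as np
import pytest

from graphvelo.containers import CellStateSet, VelocityField, build_knn_graph


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_dataset(rng):
    """50 cells, 4 features, a smooth curve plus mild scatter."""
    t = np.sort(rng.uniform(0, 1, 50))
    x = np.column_stack([
        np.cos(2 * t), np.sin(2 * t), t**2, 0.5 * t,
    ]) + 0.01 * rng.normal(size=(50, 4))
    v = np.column_stack([
        -2 * np.sin(2 * t), 2 * np.cos(2 * t), 2 * t, np.full_like(t, 0.5),
    ])
    states = CellStateSet(x, [f"g{i}" for i in range(4)],
                          [f"c{i}" for i in range(50)])
    return states, VelocityField(v)


@pytest.fixture
def small_graph(small_dataset):
    states, _ = small_dataset
    return build_knn_graph(states, k=4)
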