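import numpy as np
import pytest

from graphvelo.containers import CellStateSet, NeighborGraph, VelocityField
from graphvelo.mack import (
    TimeVector,
    cell_specific_rates,
    mack_score,
    modality_fraction,
    select_mack_genes,
)


def chain_fixture(x_col, v_col, k=2):
    """Cells on a time line 0..n-1 with a k-NN chain graph."""
    n = len(x_col)
    x = np.asarray(x_col, dtype=float)[:, None]
    states = CellStateSet(x, ["g"], [f"c{i}" for i in range(n)])
    idx = np.empty((n, k), dtype=int)
    dist = np.empty((n, k))
    for i in range(n):
        others = sorted((j for j in range(n) if j != i),
                        key=lambda j: (abs(j - i), j))
        idx[i] = others[:k]
        dist[i] = [abs(j - i) for j in idx[i]]
    graph = NeighborGraph(k=k, indices=idx, distances=dist)
    vel = VelocityField(np.asarray(v_col, dtype=float)[:, None])
    return states, vel, graph, TimeVector(np.arange(n, dtype=float))


def test_monotone_gene_scores_exactly_one():
    x = np.arange(10, dtype=float)
    states, vel, graph, t = chain_fixture(x, np.ones(10))
    res = mack_score(states, vel, t, graph)
    assert res.scores[0] == 1.0


def test_negated_velocity_scores_exactly_zero():
    x = np.arange(10, dtype=float)
    states, vel, graph, t = chain_fixture(x, -np.ones(10))
    res = mack_score(states, vel, t, graph)
    assert res.scores[0] == 0.0


def test_three_of_five_fixture_scores_exactly_point_six():
    # searched fixture: all-to-all graph (k=5), t = 0..5, v = +1; every cell
    # has exactly 3 of 5 neighbor slopes agreeing in sign
    x = np.array([2.0, 1.0, 0.0, 5.0, 4.0, 3.0])
    n = 6
    states = CellStateSet(x[:, None], ["g"], [f"c{i}" for i in range(n)])
    idx = np.array([[j for j in range(n) if j != i] for i in range(n)])
    dist = np.tile(np.arange(1.0, 6.0), (n, 1))
    graph = NeighborGraph(k=5, indices=idx, distances=dist)
    res = mack_score(states, VelocityField(np.ones((n, 1))),
                     TimeVector(np.arange(n, dtype=float)), graph)
    assert res.scores[0] == 0.6


def test_score_antisymmetry_without_zeros(rng):
    """With strict handling and no zero signs, score(v) + score(-v) = 1."""
    n = 40
    x = rng.normal(size=(n, 3))
    states = CellStateSet(x, ["a", "b", "c"], [f"c{i}" for i in range(n)])
    from graphvelo.containers import build_knn_graph

    graph = build_knn_graph(states, k=5)
    t = TimeVector(np.arange(n, dtype=float))
    v = rng.normal(size=(n, 3))
    s_pos = mack_score(states, VelocityField(v), t, graph,
                       zero_handling="strict").scores
    s_neg = mack_score(states, VelocityField(-v), t, graph,
                       zero_handling="strict").scores
    assert np.allclose(s_pos + s_neg, 1.0)


def test_monotone_transform_invariance(rng):
    """MacK depends only on slope signs, so any strictly increasing per-gene
    transform of expression leaves scores unchanged."""
    n = 40
    x = rng.uniform(0.1, 5.0, size=(n, 2))
    v = rng.normal(size=(n, 2))
    from graphvelo.containers import build_knn_graph

    states = CellStateSet(x, ["a", "b"], [f"c{i}" for i in range(n)])
    graph = build_knn_graph(states, k=6)
    t = TimeVector(rng.permutation(n).astype(float))
    base = mack_score(states, VelocityField(v), t, graph).scores
    warped = CellStateSet(np.column_stack([np.exp(x[:, 0]), x[:, 1] ** 3]),
                          ["a", "b"], states.cell_ids)
    warped_scores = mack_score(warped, VelocityField(v), t, graph).scores
    assert np.array_equal(base, warped_scores)


def test_abstain_vs_strict_zero_handling():
    # gene constant in expression, nonzero velocity: slope sign 0 vs v sign 1
    x = np.zeros(6)
    states, vel, graph, t = chain_fixture(x, np.ones(6))
    abstain = mack_score(states, vel, t, graph, zero_handling="abstain")
    strict = mack_score(states, vel, t, graph, zero_handling="strict")
    assert abstain.scores[0] == 0.0          # no evaluable pair -> 0 by rule
    assert abstain.n_evaluated[0] == 0
    assert strict.scores[0] == 0.0           # all pairs counted, none match
    assert strict.n_evaluated[0] > 0


def test_both_zero_counts_as_match():
    x = np.zeros(6)
    states, vel, graph, t = chain_fixture(x, np.zeros(6))
    res = mack_score(states, vel, t, graph)
    assert res.scores[0] == 1.0


def test_zero_dt_pairs_skipped():
    x = np.arange(6, dtype=float)
    states, vel, graph, _ = chain_fixture(x, np.ones(6))
    t = TimeVector(np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0]))
    res = mack_score(states, vel, t, graph)
    assert np.isfinite(res.scores[0])


def test_select_mack_genes_modes():
    from graphvelo.mack import MacKResult

    res = MacKResult(gene_ids=["b", "a", "c"],
                     scores=np.array([0.9, 0.9, 0.2]),
                     cell_scores=np.zeros((1, 3)),
                     n_evaluated=np.ones(3, dtype=int))
    assert select_mack_genes(res, top_n=2) == ["a", "b"]  # tie -> id order
    assert select_mack_genes(res, threshold=0.5) == ["a", "b"]
    with pytest.raises(ValueError):
        select_mack_genes(res)
    with pytest.raises(ValueError):
        select_mack_genes(res, top_n=1, threshold=0.5)
    with pytest.warns(RuntimeWarning):
        assert select_mack_genes(res, top_n=10) == ["a", "b", "c"]


def test_cell_specific_rates_invert_the_ode(rng):
    n = 200
    alpha = rng.uniform(1.0, 4.0, n)
    gamma = rng.uniform(0.5, 2.0, n)
    beta = 1.3
    u = rng.uniform(0.5, 3.0, n)
    s = rng.uniform(0.5, 3.0, n)
    du = alpha - beta * u
    ds = beta * u - gamma * s
    rates = cell_specific_rates(u, s, du, ds, beta=beta)
    assert np.allclose(rates.alpha, alpha)
    assert np.allclose(rates.gamma, gamma)
    assert rates.gamma_defined.all()


def test_cell_specific_rates_floor_flags_nan():
    rates = cell_specific_rates(np.array([1.0, 1.0]),
                                np.array([1.0, 1e-12]),
                                np.zeros(2), np.zeros(2))
    assert rates.gamma_defined[0] and not rates.gamma_defined[1]
    assert np.isnan(rates.gamma[1])


def test_modality_fraction():
    x = np.array([[1.0, 3.0, 6.0], [0.0, 0.0, 0.0]])
    states = CellStateSet(x, ["viral_1", "host_1", "host_2"], ["c0", "c1"])
    frac = modality_fraction(states, ["viral_1"])
    assert np.isclose(frac[0], 0.1)
    assert frac[1] == 0.0  # zero-total cell
    with pytest.raises(KeyError):
        modality_fraction(states, ["missing"])
    with pytest.raises(ValueError):
        modality_fraction(states, [])
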