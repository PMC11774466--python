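import numpy as np
import pytest

from graphvelo.mack import TimeVector
from graphvelo.trends import (
    VelocityTrend,
    cluster_trends,
    dtw_decoupling,
    dtw_distance,
    elbow_index,
    fit_velocity_trend,
)


def test_trend_recovers_smooth_function(rng):
    t = np.sort(rng.uniform(0, 1, 300))
    y = np.sin(2 * np.pi * t) + 0.05 * rng.normal(size=300)
    tr = fit_velocity_trend(TimeVector(t), y)
    assert tr.grid.size == 100
    truth = np.sin(2 * np.pi * tr.grid)
    assert np.sqrt(np.mean((tr.fitted - truth) ** 2)) < 0.05


def test_trend_fits_constant(rng):
    t = np.sort(rng.uniform(0, 1, 100))
    tr = fit_velocity_trend(TimeVector(t), np.full(100, 2.5))
    assert np.allclose(tr.fitted, 2.5, atol=1e-6)


def test_trend_input_validation(rng):
    t = np.sort(rng.uniform(0, 1, 10))
    with pytest.raises(ValueError):
        fit_velocity_trend(TimeVector(t), np.ones(10))  # too few cells
    with pytest.raises(ValueError):
        fit_velocity_trend(TimeVector(np.linspace(0, 1, 30)), np.ones(29))
    with pytest.raises(ValueError):
        TimeVector(np.ones(30))  # constant axis rejected at the source


def brute_force_dtw(a, b):
    """Independent recursive implementation with memoization."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0 and j == 0:
            return (a[0] - b[0]) ** 2
        if i == 0:
            return d(0, j - 1) + (a[0] - b[j]) ** 2
        if j == 0:
            return d(i - 1, 0) + (a[i] - b[0]) ** 2
        return min(d(i - 1, j - 1), d(i - 1, j), d(i, j - 1)) + \
            (a[i] - b[j]) ** 2

    return np.sqrt(d(len(a) - 1, len(b) - 1))


def test_dtw_matches_independent_oracle(rng):
    for _ in range(5):
        a = rng.normal(size=12)
        b = rng.normal(size=9)
        assert np.isclose(dtw_distance(a, b), brute_force_dtw(tuple(a),
                                                              tuple(b)))


def test_dtw_identical_series_is_zero(rng):
    a = rng.normal(size=20)
    assert dtw_distance(a, a) == 0.0


def test_dtw_shift_invariance_of_warping():
    # a pure time shift is mostly absorbed by warping, unlike euclidean
    t = np.linspace(0, 1, 50)
    a = np.sin(2 * np.pi * t)
    b = np.sin(2 * np.pi * (t - 0.05))
    assert dtw_distance(a, b) < np.sqrt(((a - b) ** 2).sum())


def test_elbow_matches_independent_oracle(rng):
    def oracle(y):
        y = np.asarray(y, dtype=float)
        x = np.arange(y.size, dtype=float)
        best, best_d = 0, -1.0
        for i in range(y.size):
            # distance from (x_i, y_i) to the line through first/last points
            x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
            num = abs((y1 - y0) * x[i] - (x1 - x0) * y[i] + x1 * y0 - y1 * x0)
            den = np.hypot(y1 - y0, x1 - x0)
            d = num / den
            if d > best_d:
                best, best_d = i, d
        return best

    for _ in range(10):
        y = np.sort(rng.exponential(size=40))
        assert elbow_index(y) == oracle(y)


def test_elbow_known_curve():
    # flat then steep: elbow at the corner
    y = np.concatenate([np.zeros(10), np.arange(1.0, 6.0)])
    assert elbow_index(y) == 9


def test_cluster_trends_two_families(rng):
    grid = np.linspace(0, 1, 100)
    trends = []
    for g in range(40):
        if g < 20:
            f = (1 + 0.1 * rng.normal()) * grid
        else:
            f = (1 + 0.1 * rng.normal()) * (1 - grid)
        trends.append(VelocityTrend(grid=grid, fitted=f, gene_id=f"g{g}"))
    clus = cluster_trends(trends, k=15, resolution=0.3, seed=0)
    labels = clus.labels
    assert len(set(labels[:20])) == 1
    assert len(set(labels[20:])) == 1
    assert labels[0] != labels[-1]
    # cluster means are pointwise means of member trends
    lab = int(labels[0])
    member = np.vstack([tr.fitted for tr, l in zip(trends, labels)
                        if l == lab])
    assert np.allclose(clus.cluster_means[lab], member.mean(axis=0))


def test_cluster_trends_needs_enough_genes():
    grid = np.linspace(0, 1, 10)
    trends = [VelocityTrend(grid=grid, fitted=grid, gene_id=f"g{i}")
              for i in range(10)]
    with pytest.raises(ValueError):
        cluster_trends(trends, k=15)


def test_dtw_decoupling_ranks_planted_outliers(rng):
    grid = np.linspace(0, 1, 60)
    a, b = [], []
    for g in range(30):
        base = np.exp(-2 * grid) + 0.01 * rng.normal(size=60)
        a.append(VelocityTrend(grid=grid, fitted=base, gene_id=f"g{g}"))
        if g < 5:  # decoupled: second modality flat
            other = np.full(60, 0.5) + 0.01 * rng.normal(size=60)
        else:
            other = base + 0.01 * rng.normal(size=60)
        b.append(VelocityTrend(grid=grid, fitted=other, gene_id=f"g{g}"))
    res = dtw_decoupling(a, b)
    assert set(res.ranked_genes[-5:]) == {f"g{g}" for g in range(5)}
    assert res.decoupled == res.ranked_genes[res.elbow + 1:]
    # distances ranked ascending
    d_sorted = np.sort(res.distances)
    assert np.allclose(
        d_sorted,
        [res.distances[res.gene_ids.index(g)] for g in res.ranked_genes])


def test_dtw_decoupling_id_mismatch(rng):
    grid = np.linspace(0, 1, 10)
    a = [VelocityTrend(grid=grid, fitted=grid, gene_id="x")]
    b = [VelocityTrend(grid=grid, fitted=grid, gene_id="y")]
    with pytest.raises(ValueError):
        dtw_decoupling(a, b)
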