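"""Core data containers and neighbor-graph primitives.

A single-cell dataset is represented here as a :class:`CellStateSet` (the cell
× feature value matrix for one representation — gene expression, chromatin
accessibility, or embedding coordinates) optionally paired with a
:class:`VelocityField` holding the per-cell time derivative of the same
features.  The discrete manifold is a :class:`NeighborGraph`: each cell's k
nearest neighbors in some representation.  Displacements ``δ_ij = x_j − x_i``
to those neighbors form the (redundant, non-orthogonal) local basis in which
velocities are expressed throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CellStateSet",
    "VelocityField",
    "NeighborGraph",
    "DisplacementBasis",
    "AlignmentError",
    "build_knn_graph",
    "displacements",
    "smooth_velocity",
]


class AlignmentError(ValueError):
    """Raised when two objects that must share cells/features do not."""


def _as_dense_float(values) -> np.ndarray:
    import scipy.sparse as sp

    if sp.issparse(values):
        values = values.toarray()
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr


@dataclass
class CellStateSet:
    """Cells × features value matrix for one data representation."""

    values: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]
    representation: str = "genes"

    def __post_init__(self):
        self.values = _as_dense_float(self.values)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n, m = self.values.shape
        if n != len(self.cell_ids):
            raise ValueError(
                f"{n} rows but {len(self.cell_ids)} cell ids"
            )
        if m != len(self.feature_ids):
            raise ValueError(
                f"{m} columns but {len(self.feature_ids)} feature ids"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("state matrix contains missing/non-finite values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, features: list[str]) -> "CellStateSet":
        idx = [self.feature_ids.index(f) for f in features]
        return CellStateSet(
            self.values[:, idx], list(features), list(self.cell_ids),
            representation=self.representation,
        )


@dataclass
class VelocityField:
    """Per-cell velocity matrix aligned with a CellStateSet."""

    values: np.ndarray
    paired_representation: str = "genes"

    def __post_init__(self):
        self.values = _as_dense_float(self.values)
        if not np.isfinite(self.values).all():
            raise ValueError("velocity matrix contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def check_paired(self, states: CellStateSet) -> None:
        if self.values.shape != states.values.shape:
            raise AlignmentError(
                f"velocity shape {self.values.shape} != state shape "
                f"{states.values.shape}"
            )


@dataclass
class NeighborGraph:
    """k-nearest-neighbor graph defining the discrete data manifold.

    ``indices[i]`` lists the k neighbors of cell i (self excluded),
    ``distances[i]`` the matching distances sorted ascending.
    """

    k: int
    indices: np.ndarray
    distances: np.ndarray
    metric: str = "euclidean"
    built_on: str = "genes"

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)
        n, k = self.indices.shape
        if k != self.k:
            raise ValueError(f"indices have {k} columns but k={self.k}")
        if self.distances.shape != (n, k):
            raise ValueError("distances shape does not match indices")
        if (self.indices == np.arange(n)[:, None]).any():
            raise ValueError("a cell lists itself as a neighbor")
        if self.indices.min() < 0 or self.indices.max() >= n:
            raise ValueError("neighbor index out of range")
        if (np.diff(self.distances, axis=1) < -1e-12).any():
            raise ValueError("distances not sorted ascending")

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]

    def check_cells(self, states: CellStateSet) -> None:
        if states.n_cells != self.n_cells:
            raise AlignmentError(
                f"graph has {self.n_cells} cells, states have {states.n_cells}"
            )


@dataclass
class DisplacementBasis:
    """Per-cell stack of displacement vectors δ_ij = x_j − x_i.

    Stored as an (n_cells, k, n_features) array in the representation the
    consumer requested, which may differ from the representation the graph
    was built on.
    """

    deltas: np.ndarray
    representation: str = "genes"

    def __post_init__(self):
        self.deltas = np.asarray(self.deltas, dtype=float)
        if self.deltas.ndim != 3:
            raise ValueError("displacement basis must be (cells, k, features)")


def build_knn_graph(states: CellStateSet, k: int = 30,
                    metric: str = "euclidean") -> NeighborGraph:
    """k nearest neighbors of every cell, self excluded.

    Ties in distance are broken by ascending cell index for reproducibility
    (duplicate cells are permitted and produce zero displacements downstream).
    """
    n = states.n_cells
    if k < 2 or k >= n:
        raise ValueError(f"k must satisfy 2 <= k < n_cells={n}, got {k}")
    if n * states.n_features <= 250_000:
        # exact brute force with deterministic lexicographic tie-break
        from scipy.spatial.distance import cdist
        d = cdist(states.values, states.values, metric=metric)
        np.fill_diagonal(d, np.inf)
        order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d), axis=1)
        idx = order[:, :k]
        dist = np.take_along_axis(d, idx, axis=1)
    else:
        nn = NearestNeighbors(n_neighbors=k + 1, metric=metric)
        nn.fit(states.values)
        dist, idx = nn.kneighbors(states.values)
        # drop self wherever it appears (may not be column 0 under ties)
        self_col = idx == np.arange(n)[:, None]
        keep_idx = np.empty((n, k), dtype=int)
        keep_dist = np.empty((n, k), dtype=float)
        for i in range(n):
            mask = ~self_col[i]
            keep_idx[i] = idx[i, mask][:k]
            keep_dist[i] = dist[i, mask][:k]
        idx, dist = keep_idx, keep_dist
    return NeighborGraph(k=k, indices=idx, distances=dist, metric=metric,
                         built_on=states.representation)


def displacements(states: CellStateSet, graph: NeighborGraph) -> DisplacementBasis:
    """Displacement vectors δ_ij = x_j − x_i to each graph neighbor."""
    graph.check_cells(states)
    x = states.values
    deltas = x[graph.indices] - x[:, None, :]
    return DisplacementBasis(deltas=deltas, representation=states.representation)


def smooth_velocity(vel: VelocityField, graph: NeighborGraph) -> VelocityField:
    """Self-inclusive neighborhood mean of the velocity vectors.

    v̄_i = mean of v over 𝓝_i ∪ {i} — the discrete analogue of ensemble
    averaging raw velocities over a cell's local neighborhood.
    """
    if vel.n_cells != graph.n_cells:
        raise AlignmentError("velocity/graph cell count mismatch")
    v = vel.values
    pooled = (v[graph.indices].sum(axis=1) + v) / (graph.k + 1)
    return VelocityField(pooled, paired_representation=vel.paired_representation)
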