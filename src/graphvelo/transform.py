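"""Moving velocity vectors between data representations.

Because the tangent coefficients φ are attached to cells (not coordinates),
the same combination applied to displacements in any other representation of
the same cells yields the velocity there:

    v‖(y_i) = Σ_{j∈𝓝_i} φ_ij (y_j − y_i).

This carries velocities from a fitted subspace to the whole feature space
(all genes, viral genes, chromatin features) or into embeddings such as PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    AlignmentError,
    CellStateSet,
    NeighborGraph,
    VelocityField,
    displacements,
)
from .tangent import TangentCoefficients, reconstruct

__all__ = [
    "RepresentationPair",
    "StepSizes",
    "transform_velocity",
    "adaptive_dt",
    "denoise_in_pca",
    "extend_to_features",
]


@dataclass
class RepresentationPair:
    """Two representations of the same cells, in the same order."""

    source: CellStateSet
    target: CellStateSet
    mapping_tag: str = ""

    def __post_init__(self):
        if self.source.cell_ids != self.target.cell_ids:
            raise AlignmentError("source/target cell ids differ or are reordered")


@dataclass
class StepSizes:
    """Per-cell extrapolation step sizes dt_i (time units of the velocity)."""

    dt: np.ndarray

    def __post_init__(self):
        self.dt = np.asarray(self.dt, dtype=float)
        if (self.dt <= 0).any():
            raise ValueError("step sizes must be positive")


def transform_velocity(
    phi: TangentCoefficients,
    pair: RepresentationPair,
    graph: NeighborGraph | None = None,
) -> VelocityField:
    """Apply fitted coefficients to target-representation displacements."""
    graph = graph or phi.graph
    graph.check_cells(pair.target)
    deltas = displacements(pair.target, graph).deltas  # (n, k, m)
    v = reconstruct(phi.phi, deltas)
    return VelocityField(v, paired_representation=pair.target.representation)


def adaptive_dt(
    states: CellStateSet, vel: VelocityField, graph: NeighborGraph
) -> StepSizes:
    """Density-adapted extrapolation step: dt_i = mean_j ‖δ_ij‖ / ‖v_i‖.

    The step keeps the extrapolated state x_i + v_i·dt_i within the local
    neighborhood scale.  Zero-speed cells get the population median dt.
    """
    graph.check_cells(states)
    vel.check_paired(states)
    mean_dist = graph.distances.mean(axis=1)
    speed = np.linalg.norm(vel.values, axis=1)
    moving = speed > 0
    if not moving.any():
        raise ValueError("all cells have zero velocity; dt undefined")
    dt = np.empty(states.n_cells)
    dt[moving] = mean_dist[moving] / speed[moving]
    dt[~moving] = np.median(dt[moving])
    return StepSizes(dt)


def denoise_in_pca(
    states: CellStateSet,
    vel: VelocityField,
    loadings: np.ndarray,
    graph: NeighborGraph,
    dt: StepSizes | None = None,
) -> VelocityField:
    """Velocity in PC space via extrapolate-then-project.

    The future state x′_i = x_i + v_i·dt_i is mapped through the loading
    matrix Q (features × PCs) and differenced back:
    v_i^PCA = (x′_i Q − x_i Q)/dt_i.  For the linear map this equals v·Q
    exactly; the two-step form is kept so nonlinear post-maps can be chained.
    """
    Q = np.asarray(loadings, dtype=float)
    if Q.shape[0] != states.n_features:
        raise AlignmentError(
            f"loadings have {Q.shape[0]} rows but states have "
            f"{states.n_features} features"
        )
    gram = Q.T @ Q
    if not np.allclose(gram, np.eye(Q.shape[1]), atol=1e-6):
        import warnings

        warnings.warn("PC loading matrix is not column-orthonormal", RuntimeWarning)
    if dt is None:
        dt = adaptive_dt(states, vel, graph)
    x = states.values
    x_future = x + vel.values * dt.dt[:, None]
    v_pca = (x_future @ Q - x @ Q) / dt.dt[:, None]
    return VelocityField(v_pca, paired_representation="pca")


def extend_to_features(
    phi: TangentCoefficients,
    full_states: CellStateSet,
    graph: NeighborGraph | None = None,
) -> VelocityField:
    """Infer velocities for every feature in ``full_states``.

    Per feature g, v_i^g = Σ_j φ_ij (x_j^g − x_i^g); with φ fitted on a
    trusted subspace (e.g. manifold-consistent genes or one modality) this is
    the whole-genome / cross-modality velocity inference.
    """
    graph = graph or phi.graph
    graph.check_cells(full_states)
    pair = RepresentationPair(source=full_states, target=full_states)
    return transform_velocity(phi, pair, graph)
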