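"""Evaluation metrics for velocity fields.

Direction is scored by per-cell cosine similarity, magnitude by RMSE over
matrix entries (per-cell norm RMSE also exposed), sign by entrywise accuracy,
and developmental plausibility by the cross-boundary correctness (CBC) score:
the mean cosine between a boundary cell's velocity and the displacements to
its neighbors inside an annotated target cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AlignmentError, CellStateSet, NeighborGraph, VelocityField

__all__ = ["VelocityEval", "ClusterAnnotation", "evaluate", "speed", "cbc_score"]

_EPS = 1e-12


@dataclass
class VelocityEval:
    cosine: np.ndarray          # per-cell, NaN where a row had zero norm
    rmse: float                 # entrywise, whole matrix
    rmse_per_cell: np.ndarray   # |‖est_i‖ − ‖true_i‖| proxy: entrywise per-cell
    accuracy: float             # fraction of entries with matching sign
    n_zero_rows: int            # rows excluded from cosine

    @property
    def median_cosine(self) -> float:
        return float(np.nanmedian(self.cosine))

    @property
    def mean_cosine(self) -> float:
        return float(np.nanmean(self.cosine))


@dataclass
class ClusterAnnotation:
    """Per-cell labels plus the expected (source, target) transitions."""

    labels: np.ndarray
    transitions: list[tuple[str, str]] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.transitions = self.transitions or []


def evaluate(vel_est: VelocityField, vel_true: VelocityField,
             sign_deadband: float = 0.0) -> VelocityEval:
    """Cosine / RMSE / sign accuracy between two aligned velocity fields.

    Rows where either field has zero norm are excluded from the cosine (their
    count is reported).  ``sign_deadband`` treats |v| < ε as zero for the
    accuracy; exact zeros match only zeros.
    """
    a, b = vel_est.values, vel_true.values
    if a.shape != b.shape:
        raise AlignmentError(f"shape mismatch {a.shape} vs {b.shape}")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na > _EPS) & (nb > _EPS)
    cosine = np.full(a.shape[0], np.nan)
    cosine[ok] = (a[ok] * b[ok]).sum(axis=1) / (na[ok] * nb[ok])

    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    rmse_per_cell = np.sqrt(np.mean((a - b) ** 2, axis=1))

    if sign_deadband > 0:
        a_s = np.where(np.abs(a) < sign_deadband, 0.0, a)
        b_s = np.where(np.abs(b) < sign_deadband, 0.0, b)
    else:
        a_s, b_s = a, b
    accuracy = float(np.mean(np.sign(a_s) == np.sign(b_s)))
    return VelocityEval(cosine=cosine, rmse=rmse, rmse_per_cell=rmse_per_cell,
                        accuracy=accuracy, n_zero_rows=int((~ok).sum()))


def accuracy_per_gene(vel_est: VelocityField, vel_true: VelocityField,
                      sign_deadband: float | np.ndarray = 0.0) -> np.ndarray:
    """Sign accuracy per feature (column) rather than pooled entrywise.

    ``sign_deadband`` treats |v| < ε as zero on both sides, as in
    :func:`evaluate`; a per-feature array of ε is also accepted (e.g. a
    known measurement-noise floor).  With the default ε=0 exact zeros match
    only zeros.
    """
    a, b = vel_est.values, vel_true.values
    if a.shape != b.shape:
        raise AlignmentError(f"shape mismatch {a.shape} vs {b.shape}")
    eps = np.asarray(sign_deadband, dtype=float)
    if np.any(eps > 0):
        a = np.where(np.abs(a) < eps, 0.0, a)
        b = np.where(np.abs(b) < eps, 0.0, b)
    return np.mean(np.sign(a) == np.sign(b), axis=0)


def speed(vel: VelocityField, feature_subset: np.ndarray | list | None = None,
          feature_ids: list[str] | None = None) -> np.ndarray:
    """Per-cell L2 velocity norm, optionally over a feature subset."""
    v = vel.values
    if feature_subset is not None:
        if len(feature_subset) == 0:
            raise ValueError("feature subset is empty")
        if feature_ids is not None and isinstance(feature_subset[0], str):
            cols = [feature_ids.index(f) for f in feature_subset]
        else:
            cols = list(feature_subset)
        v = v[:, cols]
    return np.linalg.norm(v, axis=1)


def cbc_score(
    states: CellStateSet,
    vel: VelocityField,
    graph: NeighborGraph,
    annotation: ClusterAnnotation,
    pair: tuple[str, str],
):
    """Cross-boundary correctness for one (source → target) cluster pair.

    For each source-cluster cell with at least one neighbor in the target
    cluster, the score is the mean cosine between its velocity and the
    displacements toward those target neighbors.  Returns
    ``(per_boundary_cell_scores, boundary_cell_index, mean)``; the mean is
    NaN (with a warning) when no boundary cell exists.
    """
    graph.check_cells(states)
    vel.check_paired(states)
    src, tgt = pair
    labels = annotation.labels
    if labels.shape[0] != states.n_cells:
        raise AlignmentError("annotation does not cover all cells")
    scores, cells = [], []
    for i in np.flatnonzero(labels == src):
        nbrs = graph.indices[i]
        into = nbrs[labels[nbrs] == tgt]
        if into.size == 0:
            continue
        v = vel.values[i]
        nv = np.linalg.norm(v)
        if nv < _EPS:
            scores.append(0.0)
            cells.append(i)
            continue
        d = states.values[into] - states.values[i]
        dn = np.linalg.norm(d, axis=1)
        keep = dn > _EPS
        if not keep.any():
            continue
        cos = (d[keep] @ v) / (dn[keep] * nv)
        scores.append(float(cos.mean()))
        cells.append(i)
    if not scores:
        import warnings

        warnings.warn(f"no boundary cells for pair {pair}", RuntimeWarning)
        return np.array([]), np.array([], dtype=int), float("nan")
    scores = np.asarray(scores)
    return scores, np.asarray(cells), float(scores.mean())
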