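"""Continuous vector-field learning in an RKHS of Gaussian bases.

The discrete (state, velocity) pairs are summarized by a smooth field
v(x) = Σ_α c_α Γ(x, x̃_α) with Γ(x, x̃) = exp(−w‖x − x̃‖²/2), fitted by
Tikhonov-regularized least squares:

    Φ(c) = Σ_i ‖v_i − Σ_α Γ(x_i, x̃_α) c_α‖² + (λ/2) Σ_{αβ} c_αᵀ Γ(x̃_α, x̃_β) c_β.

The Gaussian expansion has an analytic Jacobian, giving per-cell acceleration
a(x) = J(x)·v(x) and, by integrating a Jacobian element over binned regulator
levels, effective dose–response curves between a regulator and an effector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .containers import CellStateSet, VelocityField

__all__ = [
    "RKHSField",
    "fit_rkhs_field",
    "field_jacobian",
    "acceleration",
    "dose_response",
]


@dataclass
class RKHSField:
    centers: np.ndarray        # (m, d)
    coefficients: np.ndarray   # (m, d_out)
    bandwidth: float           # w in exp(-w r^2 / 2)
    ridge: float

    def __post_init__(self):
        if self.bandwidth <= 0:
            raise ValueError("bandwidth w must be positive")
        if self.centers.shape[0] != self.coefficients.shape[0]:
            raise ValueError("one coefficient vector per center required")

    def _kernel(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        sq = cdist(x, self.centers, "sqeuclidean")
        return np.exp(-0.5 * self.bandwidth * sq)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the field at points x (n, d) -> (n, d_out)."""
        return self._kernel(x) @ self.coefficients


def median_bandwidth(states: np.ndarray) -> float:
    """Median heuristic: w = 1 / median²(pairwise distances)."""
    x = np.asarray(states, dtype=float)
    if x.shape[0] > 1500:
        rng = np.random.default_rng(0)
        x = x[rng.choice(x.shape[0], 1500, replace=False)]
    med = np.median(pdist(x))
    if med == 0:
        raise ValueError("median pairwise distance is zero")
    return 1.0 / med**2


def fit_rkhs_field(
    states: CellStateSet,
    vel: VelocityField,
    n_centers: int = 500,
    w: float | None = None,
    ridge: float = 1e-5,
    seed: int = 0,
) -> RKHSField:
    """Closed-form fit of the regularized RKHS expansion.

    Centers are a uniform random subsample of the training states (all states
    when ``n_centers`` ≥ n_cells); ``w`` defaults to the median heuristic.
    With ridge = 0 and a singular system a jitter ridge of 1e-10 is applied
    with a warning.
    """
    X = states.values
    V = vel.values
    if X.shape[0] != V.shape[0]:
        raise ValueError("states and velocities have different cell counts")
    if w is None:
        w = median_bandwidth(X)
    rng = np.random.default_rng(seed)
    if n_centers >= X.shape[0]:
        centers = X.copy()
    else:
        centers = X[rng.choice(X.shape[0], n_centers, replace=False)]

    K = np.exp(-0.5 * w * cdist(X, centers, "sqeuclidean"))       # (n, m)
    G = np.exp(-0.5 * w * cdist(centers, centers, "sqeuclidean"))  # (m, m)
    A = K.T @ K + 0.5 * ridge * G
    try:
        C = np.linalg.solve(A, K.T @ V)
    except np.linalg.LinAlgError:
        warnings.warn("singular normal equations; applying jitter ridge 1e-10",
                      RuntimeWarning)
        C = np.linalg.solve(A + 1e-10 * np.eye(A.shape[0]), K.T @ V)
    return RKHSField(centers=centers, coefficients=C, bandwidth=w, ridge=ridge)


def field_jacobian(field: RKHSField, x: np.ndarray) -> np.ndarray:
    """Analytic Jacobian J[d, e] = ∂v_d/∂x_e at a single point x.

    ∂Γ(x, x̃_α)/∂x_e = −w (x_e − x̃_{α,e}) Γ(x, x̃_α).
    """
    x = np.asarray(x, dtype=float).ravel()
    gamma = field._kernel(x[None, :]).ravel()           # (m,)
    diff = x[None, :] - field.centers                    # (m, d)
    dgamma = -field.bandwidth * diff * gamma[:, None]    # (m, d) = dΓ/dx_e
    # J[d_out, e] = sum_alpha c[alpha, d_out] * dgamma[alpha, e]
    return field.coefficients.T @ dgamma


def acceleration(field: RKHSField, x: np.ndarray) -> np.ndarray:
    """a(x) = J(x) · v(x), the convective derivative of the field."""
    x = np.asarray(x, dtype=float).ravel()
    return field_jacobian(field, x) @ field(x[None, :]).ravel()


def dose_response(
    field: RKHSField,
    regulator: int,
    effector: int,
    states: CellStateSet,
    n_grid: int = 100,
):
    """Effective dose–response of an effector to a regulator.

    Cells are binned by min–max-normalized regulator level into ``n_grid``
    bins; the mean Jacobian element ∂v_effector/∂x_regulator per bin (empty
    bins linearly interpolated) is integrated cumulatively (trapezoid,
    anchored at 0 at the lowest bin).  Returns ``(grid, curve, mean_element)``.
    """
    x_reg = states.values[:, regulator]
    if np.ptp(x_reg) == 0:
        raise ValueError("regulator expression is constant")
    level = (x_reg - x_reg.min()) / np.ptp(x_reg)
    elements = np.array([
        field_jacobian(field, xi)[effector, regulator] for xi in states.values
    ])
    grid = np.linspace(0.0, 1.0, n_grid)
    bins = np.clip(np.digitize(level, grid) - 1, 0, n_grid - 1)
    mean_el = np.full(n_grid, np.nan)
    for b in range(n_grid):
        mask = bins == b
        if mask.any():
            mean_el[b] = elements[mask].mean()
    filled = np.flatnonzero(~np.isnan(mean_el))
    mean_el = np.interp(np.arange(n_grid), filled, mean_el[filled])
    curve = np.concatenate([
        [0.0],
        np.cumsum(0.5 * (mean_el[1:] + mean_el[:-1]) * np.diff(grid)),
    ])
    return grid, curve, mean_el
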