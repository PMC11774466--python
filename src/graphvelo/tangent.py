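"""Tangent-space projection of velocity vectors onto the data manifold.

A velocity vector measured for cell i is re-expressed as a linear combination
of the displacement vectors to its graph neighbors,

    v‖_i = Σ_{j∈𝓝_i} φ_ij δ_ij ,        δ_ij = x_j − x_i ,

so that the result lies in the local tangent plane spanned by observed
neighboring states.  The coefficients φ_i minimize, per cell, the loss

    L(φ_i) = ‖v_i − Σ_j φ_ij δ_ij‖²  −  b · cos(φ_i, φ^corr_i)  +  λ‖φ_i‖² ,

where φ^corr_i are the heuristic cosine-kernel coefficients (the cosine
between v_i and each δ_ij).  The squared-error term retains the velocity
magnitude, the cosine term anchors the solution to the direction the cosine
kernel is known to recover asymptotically, and the L2 term bounds φ.  Cells
are independent; each solve is a small bounded quasi-Newton minimization
initialized at the ridge least-squares solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .containers import (
    CellStateSet,
    DisplacementBasis,
    NeighborGraph,
    VelocityField,
    displacements,
    smooth_velocity,
)

__all__ = [
    "TSPConfig",
    "TangentCoefficients",
    "cosine_kernel_coefficients",
    "tsp_loss",
    "tsp_project",
]

_EPS = 1e-12


def reconstruct(phi: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    """v‖_i = Σ_j φ_ij δ_ij for all cells; shared by projection/transform so
    both produce bitwise-identical output on identical inputs."""
    return np.einsum("nk,nkm->nm", phi, deltas)


@dataclass
class TSPConfig:
    """Hyperparameters of the tangent-space-projection loss and solver.

    b weights the direction-retention (cosine) term; lam is the L2 ridge
    weight λ.  Defaults were chosen by a coarse grid on the shipped sphere
    benchmark (see scripts/choose_tsp_defaults.py).
    """

    b: float = 1.0
    lam: float = 0.5
    solver: str = "l-bfgs-b"
    max_iter: int = 200
    tol: float = 1e-6
    init: str = "ridge"
    presmooth: bool = False

    def __post_init__(self):
        if self.b < 0 or self.lam < 0 or self.tol <= 0:
            raise ValueError("require b >= 0, lam >= 0, tol > 0")


@dataclass
class TangentCoefficients:
    """Per-cell coefficient vectors φ over graph neighbors (cells × k)."""

    phi: np.ndarray
    representation: str
    graph: NeighborGraph
    converged: np.ndarray | None = None

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (self.graph.n_cells, self.graph.k):
            raise ValueError("phi must be (n_cells, k) for the fitting graph")
        if not np.isfinite(self.phi).all():
            raise ValueError("phi contains non-finite entries")


def cosine_kernel_coefficients(v_i: np.ndarray, basis_i: np.ndarray) -> np.ndarray:
    """Cosine-kernel coefficients: cos(v_i, δ_ij) for each neighbor j.

    Zero-norm displacements or a zero velocity give coefficient 0.  Raises if
    every displacement has zero norm (degenerate basis).
    """
    v_i = np.asarray(v_i, dtype=float)
    basis_i = np.asarray(basis_i, dtype=float)
    dnorm = np.linalg.norm(basis_i, axis=1)
    if np.all(dnorm < _EPS):
        raise ValueError("degenerate basis: all displacement vectors are zero")
    vnorm = np.linalg.norm(v_i)
    if vnorm < _EPS:
        return np.zeros(basis_i.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (basis_i @ v_i) / (dnorm * vnorm)
    cos[dnorm < _EPS] = 0.0
    return cos


def _safe_cos(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < _EPS or nb < _EPS:
        return 0.0
    return float(a @ b) / (na * nb)


def tsp_loss(phi_i, v_i, basis_i, phi_corr_i, cfg: TSPConfig) -> float:
    """Evaluate the per-cell TSP loss at coefficients φ_i.

    The cosine term is defined as 0 when either argument has zero norm.
    """
    phi_i = np.asarray(phi_i, dtype=float)
    resid = v_i - basis_i.T @ phi_i
    return (
        float(resid @ resid)
        - cfg.b * _safe_cos(phi_i, np.asarray(phi_corr_i, dtype=float))
        + cfg.lam * float(phi_i @ phi_i)
    )


def _ridge_init(D: np.ndarray, v: np.ndarray, lam: float) -> np.ndarray:
    """Ridge least squares: argmin ‖v − Dᵀφ‖² + λ‖φ‖² (λ→0: min-norm LS)."""
    k = D.shape[0]
    G = D @ D.T + max(lam, 1e-10) * np.eye(k)
    try:
        return np.linalg.solve(G, D @ v)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(D.T, v, rcond=None)[0]


def _loss_and_grad(phi, v, D, phi_corr, b, lam):
    resid = v - D.T @ phi
    loss = resid @ resid + lam * (phi @ phi)
    grad = -2.0 * (D @ resid) + 2.0 * lam * phi
    if b > 0.0:
        npc = np.linalg.norm(phi_corr)
        nph = np.linalg.norm(phi)
        if npc > _EPS and nph > _EPS:
            c = (phi @ phi_corr) / (nph * npc)
            loss -= b * c
            grad -= b * (phi_corr / (nph * npc) - c * phi / nph**2)
    return loss, grad


def tsp_project(
    states: CellStateSet,
    vel: VelocityField,
    graph: NeighborGraph,
    cfg: TSPConfig | None = None,
    basis: DisplacementBasis | None = None,
):
    """Project every cell's velocity onto its local tangent space.

    Returns ``(TangentCoefficients, VelocityField)`` where the velocity field
    is v‖_i = Σ_j φ_ij δ_ij in the representation of ``states``.  Cells with
    zero velocity are skipped (φ=0, v‖=0).  Non-convergent cells keep the
    best iterate and are flagged in ``TangentCoefficients.converged``.
    """
    cfg = cfg or TSPConfig()
    graph.check_cells(states)
    vel.check_paired(states)
    if not np.isfinite(vel.values).all():
        raise ValueError("velocity field contains non-finite entries")
    if cfg.presmooth:
        vel = smooth_velocity(vel, graph)
    if basis is None:
        basis = displacements(states, graph)

    n, k = graph.n_cells, graph.k
    phi = np.zeros((n, k))
    converged = np.ones(n, dtype=bool)
    n_failed = 0

    for i in range(n):
        v = vel.values[i]
        if np.linalg.norm(v) < _EPS:
            continue
        D = basis.deltas[i]  # (k, n_features)
        if not np.any(np.abs(D) > _EPS):
            continue  # duplicate-cell neighborhood: no tangent basis, v‖ = 0
        phi0 = _ridge_init(D, v, cfg.lam)
        if cfg.b == 0.0:
            # loss is a quadratic; the ridge solution is exact
            phi[i] = phi0
        else:
            phi_corr = cosine_kernel_coefficients(v, D)
            res = minimize(
                _loss_and_grad, phi0, args=(v, D, phi_corr, cfg.b, cfg.lam),
                jac=True, method="L-BFGS-B",
                options={"maxiter": cfg.max_iter, "gtol": cfg.tol},
            )
            f0, _ = _loss_and_grad(phi0, v, D, phi_corr, cfg.b, cfg.lam)
            # solver contract: never return a worse point than the init
            phi[i] = res.x if res.fun <= f0 else phi0
            if not res.success:
                converged[i] = False
                n_failed += 1

    if n_failed:
        warnings.warn(
            f"TSP solver did not converge for {n_failed}/{n} cells; "
            "best iterates returned", RuntimeWarning,
        )
    coeffs = TangentCoefficients(
        phi=phi, representation=states.representation, graph=graph,
        converged=converged,
    )
    # same arithmetic path as transform_velocity so that transforming to the
    # identity representation is bit-exact
    vpar = reconstruct(phi, basis.deltas)
    return coeffs, VelocityField(vpar, paired_representation=states.representation)
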