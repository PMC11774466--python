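"""Ground-truth synthetic data generators.

Three families of benchmarks, each with exact model drift recorded as the
true velocity at every sampled state:

* a two-gene toggle switch (mutual inhibition + self-activation via Hill
  kinetics) simulated deterministically or with the Gillespie algorithm, and
  its lift onto a sphere so that the 2-D bifurcation becomes a curved 2-D
  manifold embedded in 3-D with known surface normals;
* splicing-kinetics ODEs producing the two classic velocity traps — a
  transcription burst (α jumps to burst_factor·α mid-trajectory) and
  miRNA-driven time-varying degradation (γ grows as the miRNA accumulates);
* a small gene-regulatory-network trajectory simulator: a cascade of
  Hill-activated expression modules laid out along a linear, cyclic, or
  bifurcating topology, emitting nascent + mature counts per gene.

plus noise injectors for corrupting velocity fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .containers import CellStateSet, VelocityField
from .mack import TimeVector

__all__ = [
    "ToggleSwitchParams",
    "SphereLift",
    "SplicingSimParams",
    "SimulationTrajectory",
    "toggle_switch_drift",
    "simulate_toggle_switch",
    "lift_to_sphere",
    "sphere_normals",
    "simulate_burst",
    "simulate_mirna_degradation",
    "simulate_grn",
    "add_noise",
]


@dataclass
class ToggleSwitchParams:
    """Hill-kinetics toggle switch; defaults give a saddle at the symmetric
    state and two stable branch states (verified by root-finding), so
    trajectories started near the origin bifurcate."""

    a1: float = 0.5
    a2: float = 0.5
    b1: float = 1.0
    b2: float = 1.0
    S1: float = 0.5
    S2: float = 0.5
    K1: float = 0.5
    K2: float = 0.5
    n: float = 4.0
    gamma1: float = 1.0
    gamma2: float = 1.0
    tau: float = 1.0
    omega: float = 25.0  # molecule-count volume scaling for Gillespie

    def __post_init__(self):
        vals = [self.a1, self.a2, self.b1, self.b2, self.S1, self.S2,
                self.K1, self.K2, self.gamma1, self.gamma2, self.tau,
                self.omega]
        if any(v <= 0 for v in vals) or self.n < 1:
            raise ValueError("toggle-switch parameters must be positive, n >= 1")


@dataclass
class SphereLift:
    r: float = 70.0
    dt: float = 1.0

    def __post_init__(self):
        if self.r <= 0 or self.dt <= 0:
            raise ValueError("require r > 0 and dt > 0")


@dataclass
class SplicingSimParams:
    """Rates for the splicing-kinetics simulations (per unit time)."""

    alpha0: float = 1.0
    beta: float = 1.0
    gamma0: float = 1.0
    k_alpha: float = 0.6     # miRNA inhibition of transcription
    k_gamma: float = 1.5     # miRNA promotion of degradation
    alpha_m: float = 0.5     # miRNA production
    gamma_m: float = 0.5     # miRNA decay
    burst_factor: float = 3.0
    burst_time: float = 10.0
    t_max: float = 20.0
    n_steps: int = 400
    seed: int = 0

    def __post_init__(self):
        if min(self.alpha0, self.beta, self.gamma0, self.alpha_m,
               self.gamma_m, self.burst_factor) <= 0:
            raise ValueError("rates and burst_factor must be positive")


@dataclass
class SimulationTrajectory:
    """Sampled states with exact model drift and sampling times."""

    states: CellStateSet
    true_velocity: VelocityField
    times: TimeVector
    labels: np.ndarray | None = None
    params: object = None
    layers: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# toggle switch

def _hill_act(x, S, n):
    xn = np.power(np.maximum(x, 0.0), n)
    return xn / (S**n + xn)


def _hill_inh(x, K, n):
    xn = np.power(np.maximum(x, 0.0), n)
    return K**n / (K**n + xn)


def toggle_switch_drift(xy: np.ndarray, p: ToggleSwitchParams,
                        counts: bool = True) -> np.ndarray:
    """Deterministic drift (ẋ, ẏ).  With ``counts=True`` the input and output
    are in molecule counts (concentration × Ω)."""
    xy = np.asarray(xy, dtype=float)
    scale = p.omega if counts else 1.0
    x = xy[..., 0] / scale
    y = xy[..., 1] / scale
    dx = p.a1 * _hill_act(x, p.S1, p.n) + p.b1 * _hill_inh(y, p.K1, p.n) - p.gamma1 * x
    dy = p.a2 * _hill_act(y, p.S2, p.n) + p.b2 * _hill_inh(x, p.K2, p.n) - p.gamma2 * y
    return np.stack([dx, dy], axis=-1) * scale / p.tau


def _gillespie_trajectory(p: ToggleSwitchParams, t_samples: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """One Gillespie run; returns counts at each requested sample time."""
    omega = p.omega
    nx, ny = 0, 0
    t = 0.0
    out = np.empty((t_samples.size, 2))
    i_sample = 0
    t_end = t_samples[-1]
    while i_sample < t_samples.size:
        x, y = nx / omega, ny / omega
        props = np.array([
            omega * (p.a1 * _hill_act(x, p.S1, p.n) + p.b1 * _hill_inh(y, p.K1, p.n)),
            p.gamma1 * nx,
            omega * (p.a2 * _hill_act(y, p.S2, p.n) + p.b2 * _hill_inh(x, p.K2, p.n)),
            p.gamma2 * ny,
        ]) / p.tau
        total = props.sum()
        t_next = t + rng.exponential(1.0 / total) if total > 0 else np.inf
        while i_sample < t_samples.size and t_samples[i_sample] < t_next:
            out[i_sample] = (nx, ny)
            i_sample += 1
        if t_next > t_end:
            break
        t = t_next
        r = rng.uniform(0, total)
        if r < props[0]:
            nx += 1
        elif r < props[:2].sum():
            nx -= 1
        elif r < props[:3].sum():
            ny += 1
        else:
            ny -= 1
    return out


def simulate_toggle_switch(
    params: ToggleSwitchParams | None = None,
    n_cells: int = 2000,
    seed: int = 0,
    engine: str = "gillespie",
    t_max: float = 8.0,
    n_traj: int = 100,
) -> SimulationTrajectory:
    """Sample cells along toggle-switch trajectories from near the origin.

    States are molecule counts (2-D); the recorded true velocity is the
    deterministic drift evaluated at each sampled state, in counts per unit
    time.  Cells are labeled by the branch (x- or y-dominant) they lie on.
    """
    params = params or ToggleSwitchParams()
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    if engine not in ("gillespie", "ode"):
        raise ValueError("engine must be 'gillespie' or 'ode'")
    rng = np.random.default_rng(seed)
    per_traj = int(np.ceil(n_cells / n_traj))
    states, times = [], []
    for _ in range(n_traj):
        t_samples = np.sort(rng.uniform(0.0, t_max, size=per_traj))
        if engine == "gillespie":
            xy = _gillespie_trajectory(params, t_samples, rng)
        else:
            x0 = rng.uniform(0.0, 0.05, size=2) * params.omega
            sol = solve_ivp(
                lambda t, z: toggle_switch_drift(z, params), (0.0, t_max), x0,
                t_eval=t_samples, rtol=1e-8, atol=1e-10, dense_output=False,
            )
            xy = sol.y.T
        states.append(xy)
        times.append(t_samples)
    xy = np.concatenate(states)[:n_cells]
    t = np.concatenate(times)[:n_cells]
    vel = toggle_switch_drift(xy, params)
    labels = np.where(xy[:, 0] >= xy[:, 1], "branch_x", "branch_y")
    cs = CellStateSet(xy, ["x", "y"], [f"cell_{i}" for i in range(len(xy))],
                      representation="toggle2d")
    return SimulationTrajectory(
        states=cs,
        true_velocity=VelocityField(vel, paired_representation="toggle2d"),
        times=TimeVector(t), labels=labels, params=params,
    )


def _sphere_z(x, y, r):
    return np.sqrt(np.maximum(r**2 - x**2 - y**2, 0.0))


def lift_to_sphere(traj2d: SimulationTrajectory,
                   lift: SphereLift | None = None) -> SimulationTrajectory:
    """Lift the planar trajectory onto the upper hemisphere z ≥ 0.

    z = max(r² − x² − y², 0)^½ and ż is obtained by finite-step propagation
    of (x, y) along the planar drift:
    ż = [z(x + ẋ·dt, y + ẏ·dt) − z(x, y)] / dt.
    """
    lift = lift or SphereLift()
    xy = traj2d.states.values
    v2 = traj2d.true_velocity.values
    if not (xy[:, 0]**2 + xy[:, 1]**2 < lift.r**2).any():
        raise ValueError("no cell lies inside the sphere radius")
    z = _sphere_z(xy[:, 0], xy[:, 1], lift.r)
    xy_next = xy + v2 * lift.dt
    z_next = _sphere_z(xy_next[:, 0], xy_next[:, 1], lift.r)
    zdot = (z_next - z) / lift.dt
    states3 = np.column_stack([xy, z])
    vel3 = np.column_stack([v2, zdot])
    cs = CellStateSet(states3, ["x", "y", "z"], list(traj2d.states.cell_ids),
                      representation="sphere3d")
    return SimulationTrajectory(
        states=cs,
        true_velocity=VelocityField(vel3, paired_representation="sphere3d"),
        times=traj2d.times, labels=traj2d.labels,
        params=(traj2d.params, lift),
    )


def sphere_normals(states: CellStateSet, r: float = 70.0) -> np.ndarray:
    """Unit outward surface normals n̂ = (x, y, z)/r of the sphere lift."""
    return states.values / r


# ---------------------------------------------------------------------------
# splicing kinetics

def simulate_burst(params: SplicingSimParams | None = None):
    """Induction trajectory with a transcription burst.

    du/dt = α(t) − βu, ds/dt = βu − γ₀s from u(0)=s(0)=0, where α jumps from
    α₀ to burst_factor·α₀ at burst_time.  Returns a dict of arrays
    (t, u, s, du_dt, ds_dt, alpha) with the exact piecewise drift.
    """
    p = params or SplicingSimParams()
    t = np.linspace(0.0, p.t_max, p.n_steps)

    def alpha_of(tv):
        return np.where(tv < p.burst_time, p.alpha0, p.burst_factor * p.alpha0)

    def rhs(tv, y):
        u, s = y
        a = p.alpha0 if tv < p.burst_time else p.burst_factor * p.alpha0
        return [a - p.beta * u, p.beta * u - p.gamma0 * s]

    sol = solve_ivp(rhs, (0.0, p.t_max), [0.0, 0.0], t_eval=t,
                    max_step=p.t_max / p.n_steps, rtol=1e-9, atol=1e-12)
    u, s = sol.y
    a = alpha_of(t)
    return {
        "t": t, "u": u, "s": s, "alpha": a,
        "du_dt": a - p.beta * u,
        "ds_dt": p.beta * u - p.gamma0 * s,
    }


def simulate_mirna_degradation(params: SplicingSimParams | None = None):
    """Repression trajectory with miRNA-driven time-varying rates.

    dm/dt = α_m − γ_m m (m(0)=0), du/dt = α₀ − k_α m − βu,
    ds/dt = βu − (γ₀ + k_γ m)s, started at the unperturbed steady state
    u(0)=α₀/β, s(0)=α₀/γ₀.  Returns arrays including the programmed
    γ(t) = γ₀ + k_γ·m(t).
    """
    p = params or SplicingSimParams()
    t = np.linspace(0.0, p.t_max, p.n_steps)

    def m_of(tv):
        return (p.alpha_m / p.gamma_m) * (1.0 - np.exp(-p.gamma_m * tv))

    def rhs(tv, y):
        u, s = y
        m = m_of(tv)
        return [p.alpha0 - p.k_alpha * m - p.beta * u,
                p.beta * u - (p.gamma0 + p.k_gamma * m) * s]

    sol = solve_ivp(rhs, (0.0, p.t_max), [p.alpha0 / p.beta, p.alpha0 / p.gamma0],
                    t_eval=t, rtol=1e-9, atol=1e-12)
    u, s = sol.y
    m = m_of(t)
    return {
        "t": t, "u": u, "s": s, "m": m,
        "alpha": p.alpha0 - p.k_alpha * m,
        "gamma": p.gamma0 + p.k_gamma * m,
        "du_dt": p.alpha0 - p.k_alpha * m - p.beta * u,
        "ds_dt": p.beta * u - (p.gamma0 + p.k_gamma * m) * s,
    }


# ---------------------------------------------------------------------------
# GRN trajectory simulator

def _module_centers(topology: str, n_modules: int, t_max: float):
    if topology == "bifurcating":
        raise AssertionError  # handled separately
    return (np.arange(n_modules) + 0.5) * t_max / n_modules


def _integrate_genes(alpha_fn, beta, gamma, t_grid):
    """Integrate du/dt = α(t) − βu, ds/dt = βu − γs for all genes at once."""
    n_genes = beta.size

    def rhs(tv, y):
        u = y[:n_genes]
        s = y[n_genes:]
        a = alpha_fn(tv)
        return np.concatenate([a - beta * u, beta * u - gamma * s])

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]),
                    np.zeros(2 * n_genes), t_eval=t_grid,
                    rtol=1e-7, atol=1e-9, method="LSODA")
    return sol.y[:n_genes].T, sol.y[n_genes:].T  # (t, genes) each


def simulate_grn(
    topology: str = "bifurcating",
    n_cells: int = 1000,
    n_genes: int = 100,
    noise_sd: float = 0.1,
    seed: int = 0,
    t_max: float = 10.0,
    n_modules: int = 5,
    flip_genes: int = 0,
) -> SimulationTrajectory:
    """Cascade-of-Hill-modules trajectory with nascent + mature layers.

    Genes are assigned round-robin to expression modules whose activities are
    smooth bumps laid out along the trajectory according to the topology
    (sequential for ``linear``, phase-shifted and periodic for ``cyclic``,
    trunk-then-branch for ``bifurcating``).  Gene g in module m is
    transcribed at α_g(t) = α_g · a_m(t)² / (0.25 + a_m(t)²) and follows the
    splicing ODE du/dt = α_g(t) − β_g u, ds/dt = β_g u − γ_g s.

    Observed states are the mature counts with Gaussian measurement noise of
    sd = ``noise_sd`` × per-gene trajectory sd (clipped at 0).  The recorded
    true velocity is the drift of the underlying clean trajectory — noise
    models the measurement, not the dynamics, so ground truth is unaffected.
    With ``noise_sd=0`` the velocity equals the drift evaluated at the
    recorded states exactly.
    With ``flip_genes`` > 0 that many genes get their recorded velocity sign
    inverted — planted manifold-inconsistent genes for scoring benchmarks.
    """
    if topology not in ("linear", "cyclic", "bifurcating"):
        raise ValueError(f"unknown topology {topology!r}")
    if n_genes < 4:
        raise ValueError("n_genes must be >= 4")
    rng = np.random.default_rng(seed)

    alpha_max = rng.uniform(2.0, 6.0, size=n_genes)
    beta = rng.uniform(0.8, 1.6, size=n_genes)
    gamma = rng.uniform(0.8, 1.6, size=n_genes)
    # activity bump sd equal to the inter-module spacing: adjacent modules
    # overlap smoothly and each gene stays transcriptionally active over a
    # substantial stretch of the trajectory (cascades, not isolated pulses)
    width = t_max / n_modules

    def gene_alpha(activity_per_gene):
        h = activity_per_gene**2 / (0.25 + activity_per_gene**2)
        return alpha_max * h

    if topology in ("linear", "cyclic"):
        module_of = np.arange(n_genes) % n_modules
        centers = _module_centers("linear", n_modules, t_max)

        if topology == "linear":
            def activity(tv):
                a = np.exp(-0.5 * ((tv - centers) / width) ** 2)
                return a[module_of]

            t0, t1 = 0.0, t_max
        else:
            period = t_max

            def activity(tv):
                d = np.abs(((tv - centers) % period + period) % period)
                d = np.minimum(d, period - d)
                a = np.exp(-0.5 * (d / width) ** 2)
                return a[module_of]

            # integrate two periods, sample the (periodic) second one
            t0, t1 = period, 2.0 * period

        def alpha_fn(tv):
            return gene_alpha(activity(tv))

        t_grid = np.linspace(0.0, t1, 801)
        u_grid, s_grid = _integrate_genes(alpha_fn, beta, gamma, t_grid)
        t_cells = np.sort(rng.uniform(t0, t1, size=n_cells))
        u = np.array([np.interp(t_cells, t_grid, u_grid[:, g]) for g in range(n_genes)]).T
        s = np.array([np.interp(t_cells, t_grid, s_grid[:, g]) for g in range(n_genes)]).T
        labels = np.full(n_cells, topology)
        alpha_at = np.array([alpha_fn(tv) for tv in t_cells])
        t_rep = t_cells - t0  # report time from the sampled window start
    else:
        # bifurcating: shared trunk modules then branch-specific modules
        n_trunk = max(1, n_modules - 2)
        t_branch = t_max * n_trunk / n_modules
        trunk_centers = (np.arange(n_trunk) + 0.5) * t_branch / n_trunk
        branch_centers = t_branch + (np.arange(2) + 0.5) * (t_max - t_branch) / 2
        groups = n_trunk + 4  # trunk modules + 2 per branch
        module_of = np.arange(n_genes) % groups

        def activity_branch(tv, branch):
            act = np.zeros(groups)
            act[:n_trunk] = np.exp(-0.5 * ((tv - trunk_centers) / width) ** 2)
            for b in range(2):
                for j in range(2):
                    midx = n_trunk + 2 * b + j
                    if b == branch:
                        act[midx] = np.exp(
                            -0.5 * ((tv - branch_centers[j]) / width) ** 2)
            return act[module_of]

        t_grid = np.linspace(0.0, t_max, 801)
        u_b, s_b, a_b = [], [], []
        for branch in range(2):
            def alpha_fn(tv, _b=branch):
                return gene_alpha(activity_branch(tv, _b))

            ug, sg = _integrate_genes(alpha_fn, beta, gamma, t_grid)
            u_b.append(ug)
            s_b.append(sg)
            a_b.append(alpha_fn)
        branch_of = rng.integers(0, 2, size=n_cells)
        t_cells = np.sort(rng.uniform(0.0, t_max, size=n_cells))
        u = np.empty((n_cells, n_genes))
        s = np.empty((n_cells, n_genes))
        alpha_at = np.empty((n_cells, n_genes))
        for i, (tv, b) in enumerate(zip(t_cells, branch_of)):
            u[i] = [np.interp(tv, t_grid, u_b[b][:, g]) for g in range(n_genes)]
            s[i] = [np.interp(tv, t_grid, s_b[b][:, g]) for g in range(n_genes)]
            alpha_at[i] = a_b[b](tv)
        labels = np.where((t_cells >= t_branch),
                          np.where(branch_of == 0, "branch_a", "branch_b"),
                          "trunk")
        t_rep = t_cells

    # ground-truth drift at the clean trajectory state, then measurement
    # noise on the observed counts only
    v_u = alpha_at - beta * u
    v_s = beta * u - gamma * s
    if noise_sd > 0:
        u = np.maximum(u + rng.normal(0, noise_sd * u.std(axis=0), size=u.shape), 0.0)
        s = np.maximum(s + rng.normal(0, noise_sd * s.std(axis=0), size=s.shape), 0.0)

    flipped = np.zeros(n_genes, dtype=bool)
    if flip_genes > 0:
        flip_idx = rng.choice(n_genes, size=flip_genes, replace=False)
        flipped[flip_idx] = True
        v_s = np.where(flipped, -v_s, v_s)
        v_u = np.where(flipped, -v_u, v_u)

    gene_ids = [f"gene_{g:03d}" for g in range(n_genes)]
    cs = CellStateSet(s, gene_ids, [f"cell_{i}" for i in range(n_cells)],
                      representation="genes")
    return SimulationTrajectory(
        states=cs,
        true_velocity=VelocityField(v_s, paired_representation="genes"),
        times=TimeVector(t_rep),
        labels=labels,
        params={"topology": topology, "noise_sd": noise_sd, "seed": seed,
                "alpha_max": alpha_max, "beta": beta, "gamma": gamma,
                "module_of": module_of, "flipped": flipped},
        layers={"nascent": u, "velocity_nascent": v_u},
    )


# ---------------------------------------------------------------------------
# noise injection

def add_noise(
    vel: VelocityField,
    mode: str = "gaussian",
    level: float = 1.0,
    seed: int = 0,
    surface_normals: np.ndarray | None = None,
) -> VelocityField:
    """Corrupt a velocity field.

    ``gaussian``: i.i.d. noise per entry with sd = level × per-gene velocity
    sd.  ``normal_component``: noise only along the supplied unit surface
    normals, with per-cell amplitude ~ N(0, (level × mean speed)²) — the
    out-of-tangent-plane corruption the projection is meant to remove.
    """
    if level == 0:
        return VelocityField(vel.values.copy(),
                             paired_representation=vel.paired_representation)
    rng = np.random.default_rng(seed)
    v = vel.values
    if mode == "gaussian":
        sd = level * v.std(axis=0)
        noisy = v + rng.normal(0.0, 1.0, size=v.shape) * sd
    elif mode == "normal_component":
        if surface_normals is None:
            raise ValueError("normal_component mode requires surface normals")
        normals = np.asarray(surface_normals, dtype=float)
        scale = level * np.linalg.norm(v, axis=1).mean()
        eps = rng.normal(0.0, scale, size=v.shape[0])
        noisy = v + eps[:, None] * normals
    else:
        raise ValueError(f"unknown noise mode {mode!r}")
    return VelocityField(noisy, paired_representation=vel.paired_representation)
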