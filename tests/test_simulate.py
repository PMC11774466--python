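import numpy as np
import pytest

from graphvelo.containers import VelocityField
from graphvelo.simulate import (
    SphereLift,
    ToggleSwitchParams,
    add_noise,
    lift_to_sphere,
    simulate_burst,
    simulate_grn,
    simulate_mirna_degradation,
    simulate_toggle_switch,
    sphere_normals,
    toggle_switch_drift,
)


def test_toggle_switch_deterministic_per_seed():
    a = simulate_toggle_switch(n_cells=100, seed=3)
    b = simulate_toggle_switch(n_cells=100, seed=3)
    c = simulate_toggle_switch(n_cells=100, seed=4)
    assert np.array_equal(a.states.values, b.states.values)
    assert not np.array_equal(a.states.values, c.states.values)


def test_toggle_switch_velocity_is_exact_drift():
    traj = simulate_toggle_switch(n_cells=150, seed=0)
    drift = toggle_switch_drift(traj.states.values, traj.params)
    assert np.array_equal(traj.true_velocity.values, drift)


def test_toggle_switch_reaches_both_branches():
    traj = simulate_toggle_switch(n_cells=1000, seed=0)
    labels = set(traj.labels)
    assert labels == {"branch_x", "branch_y"}


def test_toggle_switch_counts_are_integers():
    traj = simulate_toggle_switch(n_cells=100, seed=0, engine="gillespie")
    assert np.array_equal(traj.states.values, np.round(traj.states.values))
    assert (traj.states.values >= 0).all()


def test_toggle_ode_engine_follows_drift():
    traj = simulate_toggle_switch(n_cells=50, seed=0, engine="ode", n_traj=5)
    # ODE trajectories are smooth; late cells sit near an attractor where
    # drift is small relative to the global scale
    speeds = np.linalg.norm(traj.true_velocity.values, axis=1)
    late = traj.times.t > 6.0
    if late.any():
        assert speeds[late].mean() < speeds.mean() + 1e-9


def test_toggle_engine_validation():
    with pytest.raises(ValueError):
        simulate_toggle_switch(engine="magic")
    with pytest.raises(ValueError):
        simulate_toggle_switch(n_cells=1)


def test_sphere_lift_geometry():
    traj = lift_to_sphere(simulate_toggle_switch(n_cells=300, seed=0),
                          SphereLift(r=70.0))
    x = traj.states.values
    # points with x^2+y^2 < r^2 lie exactly on the sphere
    inside = x[:, 0] ** 2 + x[:, 1] ** 2 < 70.0 ** 2
    radius = np.linalg.norm(x[inside], axis=1)
    assert np.allclose(radius, 70.0)
    normals = sphere_normals(traj.states, r=70.0)
    assert np.allclose(np.linalg.norm(normals[inside], axis=1), 1.0)


def test_sphere_lift_velocity_nearly_tangent():
    traj = lift_to_sphere(simulate_toggle_switch(n_cells=500, seed=0))
    normals = sphere_normals(traj.states)
    v = traj.true_velocity.values
    speed = np.linalg.norm(v, axis=1)
    keep = speed > 1e-9
    ratio = np.abs((v * normals).sum(axis=1))[keep] / speed[keep]
    # finite-step lift: tangent up to O(dt) curvature terms
    assert np.median(ratio) < 0.15


def test_burst_trap_geometry():
    """After the burst the phase point sits above the pre-burst steady-state
    line u = (gamma0/beta) s with positive du/dt (induction-like signature
    although rates never changed direction)."""
    sim = simulate_burst()
    post = sim["t"] > 10.0
    above = sim["u"] > (1.0 / 1.0) * sim["s"]  # gamma0 = beta = 1
    rising = sim["du_dt"] > 0
    assert (post & above & rising).any()


def test_burst_pre_burst_at_steady_state():
    sim = simulate_burst()
    # relaxation is exponential (rate 1/time unit): by t > 8 the residual
    # drift is below e^-8 of the initial scale
    pre = (sim["t"] > 8.0) & (sim["t"] < 10.0)
    assert np.allclose(sim["du_dt"][pre], 0.0, atol=1e-3)
    assert np.allclose(sim["ds_dt"][pre], 0.0, atol=1e-2)


def test_mirna_trap_geometry():
    """miRNA-boosted degradation: points above the naive steady-state line
    that nevertheless have negative true ds/dt."""
    sim = simulate_mirna_degradation()
    above = sim["u"] > (1.0 / 1.0) * sim["s"]  # naive gamma0/beta line
    falling = sim["ds_dt"] < 0
    assert (above & falling).any()


def test_mirna_gamma_program():
    sim = simulate_mirna_degradation()
    # gamma(t) = gamma0 + k_gamma * m(t), increasing from gamma0
    assert np.isclose(sim["gamma"][0], 1.0)
    assert (np.diff(sim["gamma"]) >= 0).all()
    assert np.allclose(sim["gamma"], 1.0 + 1.5 * sim["m"])


def test_grn_zero_noise_velocity_is_exact_drift():
    traj = simulate_grn("linear", n_cells=200, n_genes=20, noise_sd=0.0,
                        seed=1)
    beta = traj.params["beta"]
    gamma = traj.params["gamma"]
    u = traj.layers["nascent"]
    s = traj.states.values
    assert np.array_equal(traj.true_velocity.values, beta * u - gamma * s)


def test_grn_deterministic_and_topologies():
    for topo in ("linear", "cyclic", "bifurcating"):
        a = simulate_grn(topo, n_cells=150, n_genes=12, seed=5)
        b = simulate_grn(topo, n_cells=150, n_genes=12, seed=5)
        assert np.array_equal(a.states.values, b.states.values)
    with pytest.raises(ValueError):
        simulate_grn("ring")
    with pytest.raises(ValueError):
        simulate_grn("linear", n_genes=2)


def test_grn_bifurcating_labels():
    traj = simulate_grn("bifurcating", n_cells=400, n_genes=12, seed=0)
    assert {"trunk", "branch_a", "branch_b"} <= set(traj.labels)


def test_grn_flip_genes_mask():
    traj = simulate_grn("bifurcating", n_cells=150, n_genes=20, seed=0,
                        flip_genes=4)
    flipped = traj.params["flipped"]
    assert flipped.sum() == 4
    clean = simulate_grn("bifurcating", n_cells=150, n_genes=20, seed=0)
    assert np.array_equal(traj.true_velocity.values[:, flipped],
                          -clean.true_velocity.values[:, flipped])
    assert np.array_equal(traj.true_velocity.values[:, ~flipped],
                          clean.true_velocity.values[:, ~flipped])


def test_grn_states_nonnegative():
    traj = simulate_grn("cyclic", n_cells=200, n_genes=15, seed=2,
                        noise_sd=0.3)
    assert (traj.states.values >= 0).all()
    assert (traj.layers["nascent"] >= 0).all()


def test_add_noise_zero_level_is_copy(rng):
    v = VelocityField(rng.normal(size=(20, 3)))
    out = add_noise(v, level=0.0)
    assert np.array_equal(out.values, v.values)
    assert out.values is not v.values


def test_add_noise_normal_component_stays_on_normal(rng):
    v = VelocityField(rng.normal(size=(30, 3)))
    normals = rng.normal(size=(30, 3))
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    out = add_noise(v, mode="normal_component", level=0.5, seed=1,
                    surface_normals=normals)
    diff = out.values - v.values
    # the perturbation of each cell is exactly parallel to its normal
    cross = np.linalg.norm(np.cross(diff, normals), axis=1)
    assert np.allclose(cross, 0.0, atol=1e-12)


def test_add_noise_validation(rng):
    v = VelocityField(rng.normal(size=(5, 2)))
    with pytest.raises(ValueError):
        add_noise(v, mode="normal_component", level=1.0)
    with pytest.raises(ValueError):
        add_noise(v, mode="salt-and-pepper")


def test_toggle_params_validation():
    with pytest.raises(ValueError):
        ToggleSwitchParams(omega=0)
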