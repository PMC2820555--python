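"""IMEX scheme: Laplacian stencil, accuracy, conservation, protocol."""

import dataclasses

import numpy as np
import pytest

import samsim as s
from samsim.geometry import MeristemGeometry
from samsim.integrator import StageOperators, run_stage, step
from samsim.model import FACX, SIGNAL, ScenarioParameters
from samsim.fixtures import single_cell_geometry, single_cell_decay_problem


def path_geometry(n=3):
    """n cells in a line — hand-checkable diffusion stencil."""
    return MeristemGeometry(
        cell_ids=np.arange(n),
        centres=np.column_stack([np.arange(n, dtype=float),
                                 np.zeros(n)]),
        edges=np.column_stack([np.arange(n - 1), np.arange(1, n)]),
        layer=np.zeros(n, dtype=int),
        competent=np.ones(n, dtype=bool),
        boundary=np.ones(n, dtype=bool),
        anchoring=np.zeros(n),
        tip_cell=0,
    )


def diffusion_only_params(params):
    """All reactions off; fields evolve by diffusion alone."""
    return dataclasses.replace(
        params, facx_basal=0.0, wus_basal=0.0, signal_production=0.0,
        stemness_production=0.0, clv3_production=0.0,
        deg_wus=0.0, deg_facx=0.0, deg_signal=0.0, deg_stemness=0.0,
        deg_clv3=0.0)


def test_laplacian_kernel_and_stencil(toy):
    lap = s.graph_laplacian(toy)
    assert np.allclose(lap @ np.full(toy.n_cells, 3.7), 0.0)
    path = path_geometry(3)
    lap3 = s.graph_laplacian(path)
    assert np.allclose(lap3 @ np.array([1.0, 0.0, 0.0]), [-1.0, 1.0, 0.0])


def test_pure_diffusion_conserves_mass(toy, params):
    p = diffusion_only_params(params)
    ops = StageOperators(toy, p, dt=0.3)
    rng = np.random.default_rng(5)
    state = np.zeros((5, toy.n_cells))
    state[SIGNAL] = rng.uniform(0.0, 1.0, toy.n_cells)
    total0 = state[SIGNAL].sum()
    noise = np.zeros(toy.n_cells)
    rhs_prev = None
    sc = ScenarioParameters()
    for _ in range(10_000):
        state, rhs_prev, _ = step(state, 0.3, ops, p, sc, toy, noise,
                                  rhs_prev)
    assert state[SIGNAL].sum() == pytest.approx(total0, rel=1e-12)
    # uniformization: the field relaxes towards its mean
    assert state[SIGNAL].std() < 1e-6


def test_pure_diffusion_stable_at_ten_times_default_dt(toy, params):
    p = diffusion_only_params(params)
    ops = StageOperators(toy, p, dt=3.0)
    state = np.zeros((5, toy.n_cells))
    state[SIGNAL, 0] = 1.0
    rhs_prev = None
    sc = ScenarioParameters()
    noise = np.zeros(toy.n_cells)
    for _ in range(2000):
        state, rhs_prev, _ = step(state, 3.0, ops, p, sc, toy, noise,
                                  rhs_prev)
    assert np.all(np.isfinite(state))
    assert state[SIGNAL].max() <= 1.0 + 1e-9


def test_linear_decay_matches_exponential_second_order(params):
    """du/dt = -d u on one isolated cell: error is O(dt^2)."""
    g = single_cell_geometry()
    rate = 0.05
    problem = single_cell_decay_problem(rate, u0=1.0)
    p = dataclasses.replace(diffusion_only_params(params), deg_signal=rate)
    sc = ScenarioParameters()
    noise = np.zeros(1)
    horizon = 60.0
    errors = {}
    for dt in (0.6, 0.3):
        ops = StageOperators(g, p, dt)
        state = np.zeros((5, 1))
        state[SIGNAL] = 1.0
        rhs_prev = None
        for _ in range(int(round(horizon / dt))):
            state, rhs_prev, _ = step(state, dt, ops, p, sc, g, noise,
                                      rhs_prev)
        errors[dt] = abs(state[SIGNAL, 0] - problem.exact(horizon))
    assert errors[0.3] < 1e-5
    ratio = errors[0.6] / errors[0.3]
    assert 3.0 < ratio < 5.0   # halving dt quarters the error


def test_zero_dynamics_is_identity(toy, params):
    p = diffusion_only_params(params)
    ops = StageOperators(toy, p, dt=0.3)
    # uniform fields (no diffusion flux) with the WUS/facX pair empty
    # (no conversion): every term of the dynamics vanishes
    state = np.zeros((5, toy.n_cells))
    state[SIGNAL] = 0.25
    out, _, _ = step(state, 0.3, ops, p, ScenarioParameters(), toy,
                     np.zeros(toy.n_cells), None)
    assert np.allclose(out, state)


def test_canonical_initial_condition(geometry):
    state = s.initial_state(geometry)
    assert np.allclose(state[FACX], 0.01)
    state[FACX] = 0.0
    assert np.all(state == 0.0)


def test_run_stage_rejects_nonpositive_duration(toy, params):
    with pytest.raises(ValueError):
        run_stage(s.initial_state(toy), 0.0, 0.3, params,
                  ScenarioParameters(), toy, np.zeros(toy.n_cells))


def test_equilibrium_is_persistent(geometry, params, wt_stage1, wt_noise):
    """Re-integrating the equilibrium leaves it unchanged."""
    assert wt_stage1.equilibrium_reached
    again = run_stage(wt_stage1.final_state.copy(), 1000.0, s.DEFAULT_DT,
                      params, s.scenario_preset("wild_type"), geometry,
                      wt_noise)
    drift = np.abs(again.final_state - wt_stage1.final_state).max()
    assert drift < 1e-6


def test_two_stage_wild_type_identity(geometry, params):
    t1, t2 = s.two_stage_protocol(geometry, params,
                                  s.scenario_preset("wild_type"),
                                  durations=(s.STAGE1_DURATION, 2000.0),
                                  seed=1)
    assert np.abs(t2.final_state - t1.final_state).max() < 1e-6


def test_trajectory_bookkeeping(toy, params):
    traj = run_stage(s.initial_state(toy), 300.0, 0.3, params,
                     ScenarioParameters(), toy, np.zeros(toy.n_cells),
                     snapshot_every=200)
    assert traj.times[0] == 0.0
    assert np.all(np.diff(traj.times) > 0)
    assert np.allclose(traj.snapshots[0], s.initial_state(toy))
    assert traj.final_time == traj.times[-1]
    assert set(traj.final_max_derivative) == set(s.SPECIES)


def test_determinism_bitwise(geometry, params):
    def run():
        noise = s.sample_anchoring_noise(geometry, params.noise_amplitude, 9)
        traj = run_stage(s.initial_state(geometry), 600.0, s.DEFAULT_DT,
                         params, s.scenario_preset("wild_type"), geometry,
                         noise)
        return traj.final_state
    a, b = run(), run()
    assert np.array_equal(a, b)


def test_save_trajectory(tmp_path, toy, params):
    traj = run_stage(s.initial_state(toy), 30.0, 0.3, params,
                     ScenarioParameters(), toy, np.zeros(toy.n_cells))
    s.save_trajectory(traj, toy, tmp_path / "run")
    assert (tmp_path / "run" / "manifest.json").exists()
    assert len(list((tmp_path / "run").glob("snapshot_*.tsv"))) \
        == len(traj.times)
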