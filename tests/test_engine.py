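"""Integrator and full-system force evaluation."""

import numpy as np
import pytest

import dpdmelt as dm
from dpdmelt.engine import compute_forces
from dpdmelt.state import Frame
from dpdmelt.topology import Topology


def _two_bead_topology():
    return Topology(
        bead_types=np.array([1, 1], np.int8),
        chain_id=np.array([0, 0]),
        bonds=np.array([[0, 1]], np.int64),
        angles=np.empty((0, 3), np.int64),
        n_head=1, n_tail=1, n_lipids=1, n_nanoparticles=0,
    )


def _free_topology(n):
    return Topology(
        bead_types=np.zeros(n, np.int8),
        chain_id=np.arange(n),
        bonds=np.empty((0, 2), np.int64),
        angles=np.empty((0, 3), np.int64),
        n_head=1, n_tail=0, n_lipids=n, n_nanoparticles=0,
    )


def test_ballistic_limit_is_exact(ff_conservative):
    # two beads far apart, no interactions: r(t+dt) = r(t) + dt v exactly
    topo = _free_topology(2)
    frame = Frame.zeros(2, 10.0)
    frame.positions[:] = [[1.0, 1.0, 1.0], [8.0, 8.0, 8.0]]
    frame.velocities[:] = [[0.3, -0.2, 0.1], [-0.1, 0.2, 0.4]]
    cfg = dm.RunConfig(dt=0.01, n_steps=1, seed=0)
    expected = frame.positions + cfg.dt * frame.velocities
    dm.step(frame, topo, ff_conservative, cfg, 0, neighbor="all")
    assert np.array_equal(frame.positions, expected)


def test_bonded_pair_oscillation_matches_fine_timestep(ff_conservative):
    # stretched bond, no thermostat: compare against integration at dt/100
    def simulate(dt, n_steps):
        topo = _two_bead_topology()
        frame = Frame.zeros(2, 20.0)
        frame.positions[:] = [[5.0, 5.0, 5.0], [6.0, 5.0, 5.0]]  # r=1.0 > rs
        cfg = dm.RunConfig(dt=dt, n_steps=n_steps, seed=0, sample_every=max(1, n_steps))
        traj, _ = dm.run(frame, topo, ff_conservative, cfg, neighbor="all")
        return traj.frames[-1].positions

    coarse = simulate(0.001, 1000)
    fine = simulate(0.00001, 100000)
    assert np.allclose(coarse, fine, atol=1e-4)


def test_momentum_conservation_long_run(ff):
    box = dm.BoxSpec(4.0, 3.0)
    n_lip = dm.lipid_count(3.0, 4.0, 13)
    topo = dm.build_lipid_topology(3, 10, n_lip)
    frame = dm.place_random_melt(topo, box, seed=2)
    frame = dm.init_velocities(frame, 1.0, seed=3)
    p0 = frame.velocities.sum(axis=0).copy()
    cfg = dm.RunConfig(n_steps=10_000, seed=4, sample_every=10_000)
    traj, _ = dm.run(frame, topo, ff, cfg)
    drift = np.abs(traj.frames[-1].velocities.sum(axis=0) - p0).max()
    assert drift / topo.n_beads < 1e-8


def test_cell_list_matches_all_pairs(ff):
    # including dissipative and hash-keyed random forces
    box = dm.BoxSpec(5.0, 3.0)
    rng = np.random.default_rng(7)
    n = 200
    topo = _free_topology(n)
    frame = Frame.zeros(n, 5.0)
    frame.positions[:] = rng.uniform(0, 5.0, (n, 3))
    frame.velocities[:] = rng.normal(size=(n, 3))
    fc, ec, vc = compute_forces(frame, topo, ff, seed=11, step_index=13, neighbor="cell")
    fa, ea, va = compute_forces(frame, topo, ff, seed=11, step_index=13, neighbor="all")
    assert np.abs(fc - fa).max() < 1e-12
    assert ec == pytest.approx(ea, abs=1e-9)
    assert np.abs(vc - va).max() < 1e-9


def test_minimum_image_pair_across_boundary(ff_conservative):
    # beads at opposite faces interact through the boundary as if adjacent
    topo = _free_topology(2)
    frame = Frame.zeros(2, 10.0)
    frame.positions[:] = [[0.1, 5.0, 5.0], [9.7, 5.0, 5.0]]  # image distance 0.4
    f, e, _ = compute_forces(frame, topo, ff_conservative, neighbor="all",
                             include_random=False, include_dissipative=False)
    expected = dm.conservative_force(np.array([0.4, 0.0, 0.0]), a=25.0)
    assert np.allclose(f[0], expected, atol=1e-12)
    assert np.allclose(f[1], -expected, atol=1e-12)


def test_run_zero_steps_returns_initial_frame(ff, small_melt):
    topo, frame, _ = small_melt
    cfg = dm.RunConfig(n_steps=0, seed=1)
    traj, trace = dm.run(frame, topo, ff, cfg)
    assert len(traj) == 1
    assert np.array_equal(traj.frames[0].positions, frame.positions)
    assert len(trace.steps) == 1


def test_run_deterministic_per_seed(ff, small_melt):
    topo, frame, _ = small_melt
    cfg = dm.RunConfig(n_steps=200, seed=42, sample_every=100)
    t1, e1 = dm.run(frame, topo, ff, cfg)
    t2, e2 = dm.run(frame, topo, ff, cfg)
    assert np.array_equal(t1.frames[-1].positions, t2.frames[-1].positions)
    assert np.array_equal(e1.total_energy, e2.total_energy)
    t3, _ = dm.run(frame, topo, ff, dm.RunConfig(n_steps=200, seed=43, sample_every=100))
    assert not np.array_equal(t1.frames[-1].positions, t3.frames[-1].positions)


def test_energy_relaxes_from_random_start(ff, small_melt):
    topo, frame, _ = small_melt
    cfg = dm.RunConfig(n_steps=2000, seed=5, sample_every=500, thermo_every=100)
    _, trace = dm.run(frame, topo, ff, cfg)
    e = trace.total_energy
    assert e[0] > e[-1]
    # late-time slope much smaller than the initial drop
    late = abs(e[-1] - e[len(e) // 2])
    assert late < 0.1 * (e[0] - e[-1])


def test_nonfinite_force_diagnostic(ff):
    topo = _two_bead_topology()
    frame = Frame.zeros(2, 10.0)
    frame.positions[:] = [[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]  # coincident bonded pair
    cfg = dm.RunConfig(dt=0.01, n_steps=1, seed=0)
    with pytest.raises(ValueError, match="bond"):
        dm.step(frame, topo, ff, cfg, 0, neighbor="all")


def test_runconfig_validation():
    with pytest.raises(Exception):
        dm.RunConfig(dt=-0.01)
    with pytest.raises(Exception):
        dm.RunConfig(lambda_vv=0.0)
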