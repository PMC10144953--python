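"""Pressure tensor, interfacial tension and peak/domain extraction."""

import numpy as np
import pytest

import dpdmelt as dm
from dpdmelt import fixtures as fx
from dpdmelt.mechanics import (
    PressureTensor,
    TensionProfile,
    peak_and_domain_summary,
    pressure_tensor,
    tension_from_tensor,
    tension_global,
    tension_profile,
    tension_series,
)
from dpdmelt.observables import AxialProfile
from dpdmelt.state import Frame
from dpdmelt.topology import Topology


def _free_topology(n, types=None):
    return Topology(
        bead_types=np.zeros(n, np.int8) if types is None else types,
        chain_id=np.arange(n),
        bonds=np.empty((0, 2), np.int64),
        angles=np.empty((0, 3), np.int64),
        n_head=1, n_tail=0, n_lipids=n, n_nanoparticles=0,
    )


def test_ideal_gas_kinetic_pressure(ff):
    # non-interacting gas at rho=3, kT=1: pxx ~ rho kT = 3
    f = fx.make_ideal_gas(3.0, 20.0, 1.0, seed=8)
    p = pressure_tensor(f.frame, f.topology, ff, conservative_only=True)
    # the kinetic part alone is the ideal-gas term
    assert np.trace(p.kinetic_part) / 3 == pytest.approx(3.0, abs=0.05)
    assert p.kinetic_part[0, 0] == pytest.approx(3.0, abs=0.05)


def test_zero_velocities_no_pairs_gives_zero_pressure(ff):
    topo = _free_topology(2)
    frame = Frame.zeros(2, 10.0)
    frame.positions[:] = [[1.0, 1.0, 1.0], [8.0, 8.0, 8.0]]
    p = pressure_tensor(frame, topo, ff, conservative_only=True)
    assert np.allclose(p.components, 0.0)


def test_three_bead_virial_matches_manual_sum(ff_conservative):
    # hand-built cluster: virial term computed pair by pair by hand
    pos = np.array([[5.0, 5.0, 5.0], [5.6, 5.0, 5.0], [5.0, 5.8, 5.3]])
    topo = _free_topology(3)
    frame = Frame.zeros(3, 10.0)
    frame.positions[:] = pos
    frame.velocities[:] = [[0.1, 0, 0], [0, -0.2, 0], [0, 0, 0.3]]
    p = pressure_tensor(frame, topo, ff_conservative, conservative_only=True)
    V = 1000.0
    manual_virial = np.zeros((3, 3))
    manual_kin = np.zeros((3, 3))
    for v in frame.velocities:
        manual_kin += np.outer(v, v)
    for i in range(3):
        for j in range(i + 1, 3):
            d = pos[i] - pos[j]
            r = np.linalg.norm(d)
            if r < 1.0:
                fvec = 25.0 * (1 - r) * d / r
                manual_virial += np.outer(fvec, d)
    assert np.abs(p.components - (manual_kin + manual_virial) / V).max() < 1e-12


def test_pressure_tensor_symmetry_and_kinetic_positivity(ff):
    f = fx.make_ideal_gas(3.0, 6.0, 1.0, seed=4)
    p = pressure_tensor(f.frame, f.topology, ff, seed=1, step_index=3)
    assert np.allclose(p.components, p.components.T, atol=1e-10)
    assert (np.linalg.eigvalsh(p.kinetic_part) >= -1e-12).all()


def test_tension_arithmetic():
    comp = np.diag([2.0, 2.0, 3.0])
    p = PressureTensor(comp, np.zeros((3, 3)), comp)
    assert tension_from_tensor(p) == pytest.approx(1.0)


def test_isotropic_fluid_tension_near_zero(ff):
    f = fx.make_ideal_gas(3.0, 8.0, 1.0, seed=2)
    cfg = dm.RunConfig(n_steps=500, seed=3, sample_every=100)
    traj, _ = dm.run(f.frame, f.topology, ff, cfg)
    series = tension_series(traj, f.topology, ff)
    assert abs(np.mean(series.sigma_z[2:])) < 0.25


def test_slab_profile_integrates_to_global(ff):
    fixture = fx.make_two_phase_slab(25.0, 100.0, D=8.0, relax_steps=300, seed=5)
    for method in ("ik", "midpoint"):
        prof = tension_profile(
            [fixture.frame], fixture.topology, fixture.forcefield,
            slab_width=0.5, method=method, seed=21,
        )
        integral = np.sum(prof.sigma_z * prof.slab_width) / 8.0
        assert integral == pytest.approx(prof.global_sigma_z, abs=1e-8)
        direct = tension_global(
            fixture.frame, fixture.topology, fixture.forcefield, seed=21
        )
        assert prof.global_sigma_z == pytest.approx(direct, abs=1e-8)


def test_homogeneous_fluid_flat_profile(ff):
    f = fx.make_ideal_gas(3.0, 8.0, 1.0, seed=2)
    cfg = dm.RunConfig(n_steps=300, seed=3, sample_every=100)
    traj, _ = dm.run(f.frame, f.topology, ff, cfg)
    prof = tension_profile(traj.frames[1:], f.topology, ff, slab_width=1.0, seed=9)
    assert np.abs(prof.sigma_z).max() < 1.5  # no systematic structure


def test_two_phase_interface_peaks(ff):
    fixture = fx.make_two_phase_slab(25.0, 100.0, D=8.0, relax_steps=500, seed=6)
    # time-average the profile over a short production run
    cfg = dm.RunConfig(n_steps=500, seed=7, sample_every=50)
    traj, _ = dm.run(fixture.frame, fixture.topology, fixture.forcefield, cfg)
    prof = tension_profile(
        traj.frames[1:], fixture.topology, fixture.forcefield, 0.5, seed=3
    )
    assert prof.global_sigma_z > 0.4  # demixed: positive interfacial tension
    # stress localises at the two interfaces z ~ 0 and z ~ D/2
    top2 = prof.slab_centers[np.argsort(prof.sigma_z)[-2:]]
    for z in top2:
        d_interface = min(abs(z - 4.0), min(z, 8.0 - z))
        assert d_interface < 1.5


def test_tension_series_running_mean_window():
    f = fx.make_ideal_gas(3.0, 5.0, 1.0, seed=2)
    ff = dm.ForceFieldParams()
    cfg = dm.RunConfig(n_steps=300, seed=3, sample_every=50)
    traj, _ = dm.run(f.frame, f.topology, ff, cfg)
    series = tension_series(traj, f.topology, ff, window=3)
    assert len(series.running_mean) == len(series.sigma_z)
    assert np.isfinite(series.sigma_z).all()


# ---------------------------------------------------------------------------
# peak classification / domain sizes
# ---------------------------------------------------------------------------

def _paper_like_profile_and_density():
    """Synthetic lamellar tension profile with the printed peak layout:
    large peaks at 3.05, 12.15, 18.24, 27.0 rc; small peaks between; head
    domains between (12.15, 18.24) and (27.0, 3.05+30)."""
    D, w = 30.0, 0.05
    z = np.arange(w / 2, D, w)
    sig = np.zeros_like(z)
    large = [3.05, 12.15, 18.24, 27.0]
    small = [7.55, 14.76, 22.35]
    for c in large:
        sig += 0.654 * np.exp(-((z - c) ** 2) / (2 * 0.3**2))
    for c in small:
        sig += 0.39 * np.exp(-((z - c) ** 2) / (2 * 0.3**2))
    prof = TensionProfile(z, sig, w, float(sig.mean()))
    edges = np.arange(0.0, D + 0.5, 0.5)
    centers = 0.5 * (edges[:-1] + edges[1:])
    head = np.zeros(len(centers))
    tail = np.zeros(len(centers))
    head_ranges = [(12.15, 18.24), (27.0, 33.05)]
    for lo, hi in head_ranges:
        m = ((centers > lo) & (centers < hi)) | ((centers + D > lo) & (centers + D < hi))
        head[m] = 3.0
    tail[head == 0] = 3.0
    dens = AxialProfile(edges, {"H": head, "T": tail})
    return prof, dens, large


def test_peak_classification_and_domain_sizes_match_layout():
    prof, dens, large = _paper_like_profile_and_density()
    pk = peak_and_domain_summary(prof, dens)
    assert np.allclose(sorted(pk.large_peak_positions), large, atol=0.06)
    assert np.allclose(sorted(pk.small_peak_positions), [7.55, 14.76, 22.35], atol=0.06)
    # brute-force oracle: consecutive large-peak gaps, classified by layout
    gaps = np.diff(large + [large[0] + 30.0])
    tail_gaps = [gaps[0], gaps[2]]   # 9.1, 8.76
    head_gaps = [gaps[1], gaps[3]]   # 6.09, 6.05
    assert pk.tail_domain_size == pytest.approx(np.mean(tail_gaps), abs=0.1)
    assert pk.head_domain_size == pytest.approx(np.mean(head_gaps), abs=0.1)
    # printed single-gap values: 9.1 (tail) and 6.09 (head), within 2.5%
    assert pk.tail_domain_size == pytest.approx(9.1, rel=0.025)
    assert pk.head_domain_size == pytest.approx(6.09, rel=0.025)
    assert pk.large_peak_mean > pk.small_peak_mean


def test_single_peak_profile_rejected():
    z = np.arange(0.25, 30.0, 0.5)
    sig = np.exp(-((z - 15.0) ** 2))
    prof = TensionProfile(z, sig, 0.5, float(sig.mean()))
    edges = np.arange(0.0, 30.5, 0.5)
    dens = AxialProfile(edges, {"H": np.ones(60), "T": np.ones(60)})
    with pytest.raises(ValueError):
        peak_and_domain_summary(prof, dens)


def test_constant_offset_leaves_peak_positions_unchanged():
    prof, dens, _ = _paper_like_profile_and_density()
    pk0 = peak_and_domain_summary(prof, dens)
    shifted = TensionProfile(
        prof.slab_centers, prof.sigma_z + 5.0, prof.slab_width, prof.global_sigma_z + 5.0
    )
    pk1 = peak_and_domain_summary(shifted, dens)
    assert np.array_equal(pk0.large_peak_positions, pk1.large_peak_positions)
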