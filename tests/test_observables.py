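"""Density profiles, orientational order and gyration analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import dpdmelt as dm
from dpdmelt import fixtures as fx
from dpdmelt.observables import (
    axial_density,
    chain_direction,
    gyration_components,
    nanoparticle_layering,
    order_parameter,
    order_parameter_scalar,
    radial_density,
    unwrap_chain,
)


# ---------------------------------------------------------------------------
# axial / radial densities
# ---------------------------------------------------------------------------

def test_uniform_gas_flat_axial_profile():
    f = fx.make_ideal_gas(3.0, 20.0, 1.0, seed=1)
    prof = axial_density(f.frame, f.topology, bin_width=1.0)
    h = prof.density_per_type["H"]
    assert h.mean() == pytest.approx(3.0, rel=1e-9)  # exact count / volume
    assert np.abs(h - 3.0).max() < 0.3  # homogeneity within sampling noise


def test_axial_count_conservation_exact():
    f = fx.make_perfect_lamella(15.0, 3, 10, 30.0)
    prof = axial_density(f.frame, f.topology, bin_width=0.25)
    D = 30.0
    for t in ("H", "T"):
        total = prof.density_per_type[t].sum() * D * D * 0.25
        n_type = int((f.topology.bead_types == {"H": 0, "T": 1}[t]).sum())
        assert total == pytest.approx(n_type, abs=1e-6)


def test_lamella_head_density_localised_at_slab_centres():
    f = fx.make_perfect_lamella(15.0, 3, 10, 30.0)
    prof = axial_density(f.frame, f.topology, bin_width=0.5)
    h = prof.density_per_type["H"]
    centers = prof.bin_centers
    near = np.zeros(len(centers), dtype=bool)
    for c in f.expectations["h_slab_centers"]:
        d = np.abs((centers - c + 15.0) % 30.0 - 15.0)
        near |= d <= 3 * 0.7
    assert h[~near].max() == 0.0
    assert h[near].sum() > 0


def test_brute_force_histogram_equivalence():
    # binned profile matches a naive per-bead loop exactly
    f = fx.make_ideal_gas(3.0, 5.0, 1.0, seed=3)
    prof = axial_density(f.frame, f.topology, bin_width=0.5)
    edges = prof.bin_edges
    naive = np.zeros(len(edges) - 1)
    for z in f.frame.positions[:, 2]:
        k = min(int(z / 0.5), len(naive) - 1)
        naive[k] += 1
    assert np.allclose(prof.density_per_type["H"] * 5.0 * 5.0 * 0.5, naive,
                       rtol=0, atol=1e-9)


def test_cylinder_radial_density_zero_outside():
    f = fx.make_perfect_cylinder(4.0, n_beads=3000, seed=2)
    prof = radial_density(f.frame, f.topology, (15.0, 15.0, 0.0), (0, 0, 1), 0.5)
    h = prof.density_per_type["H"]
    centers = prof.bin_centers
    assert h[centers > 4.25].max() == 0.0
    inner = h[centers < 3.5]
    assert np.abs(inner - f.expectations["inner_density"]).max() < 0.4


def test_radial_count_conservation():
    f = fx.make_perfect_cylinder(4.0, n_beads=3000, seed=2)
    prof = radial_density(f.frame, f.topology, (15.0, 15.0, 0.0), (0, 0, 1), 0.5)
    edges = prof.bin_edges
    vol = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * 30.0
    assert (prof.density_per_type["H"] * vol).sum() == pytest.approx(3000, abs=1e-6)


def test_degenerate_axis_rejected():
    f = fx.make_ideal_gas(3.0, 5.0, 1.0, seed=0)
    with pytest.raises(ValueError):
        radial_density(f.frame, f.topology, (0, 0, 0), (0, 0, 0), 0.5)


# ---------------------------------------------------------------------------
# chain direction and order parameter
# ---------------------------------------------------------------------------

def test_chain_direction_cardinal_axes():
    chain_z = np.array([[0, 0, 0], [0, 0, 0.7], [0, 0, 1.4]])
    assert np.allclose(chain_direction(chain_z), [0, 0, 1])
    chain_x = np.array([[0, 0, 0], [0.7, 0, 0], [1.4, 0, 0]])
    assert np.allclose(chain_direction(chain_x), [1, 0, 0])


def test_chain_direction_across_periodic_boundary():
    D = 10.0
    unwrapped = np.array([[5.0, 5.0, 9.0], [5.0, 5.0, 9.8], [5.0, 5.0, 10.6]])
    wrapped = unwrapped % D
    assert np.allclose(
        chain_direction(wrapped, box_length=D), chain_direction(unwrapped)
    )


def test_chain_direction_rejects_coincident_endpoints():
    with pytest.raises(ValueError):
        chain_direction(np.zeros((2, 3)))


def test_order_parameter_analytic_values():
    para = fx.make_oriented_chains(200, 0.0, seed=1)
    assert order_parameter(para.frame, para.topology, 30.0).p2[0] == pytest.approx(1.0)
    perp = fx.make_oriented_chains(200, np.pi / 2, seed=1)
    assert order_parameter(perp.frame, perp.topology, 30.0).p2[0] == pytest.approx(-0.5)


def test_order_parameter_empty_bins_are_nan():
    f = fx.make_oriented_chains(50, 0.0, seed=1, D=30.0)
    # confine all chains to the lower half so upper-z bins are empty
    f.frame.positions[:, 2] *= 0.4
    prof = order_parameter(f.frame, f.topology, bin_width=5.0)
    assert np.isnan(prof.p2[prof.n_chains == 0]).all()
    assert not np.isnan(prof.p2[prof.n_chains > 0]).any()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_order_parameter_bounds(seed):
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(100, 3))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    p2 = order_parameter_scalar(dirs)
    assert -0.5 - 1e-12 <= p2 <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# gyration tensor
# ---------------------------------------------------------------------------

def test_gyration_single_bead_is_zero():
    f = fx.make_collinear_chain(n_beads=1)
    g = gyration_components(f.frame, f.topology)
    assert g.rg_xx[0] == g.rg_yy[0] == g.rg_zz[0] == 0.0


def test_gyration_collinear_closed_form():
    f = fx.make_collinear_chain(13, 0.7)
    g = gyration_components(f.frame, f.topology)
    assert g.rg_zz[0] == pytest.approx(fx.collinear_rg(13, 0.7), rel=1e-12)
    assert g.rg_xx[0] == 0.0 and g.rg_yy[0] == 0.0


def test_gyration_rotation_swaps_components():
    # rotating by 90 deg about x maps z -> y
    f = fx.make_collinear_chain(13, 0.7)
    g0 = gyration_components(f.frame, f.topology)
    rot = Rotation.from_euler("x", 90, degrees=True).as_matrix()
    center = np.full(3, 7.5)
    f.frame.positions[:] = (f.frame.positions - center) @ rot.T + center
    f.frame.wrap()
    g1 = gyration_components(f.frame, f.topology)
    assert g1.rg_yy[0] == pytest.approx(g0.rg_zz[0], abs=1e-9)
    assert g1.rg_zz[0] == pytest.approx(g0.rg_yy[0], abs=1e-9)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_gyration_rigid_motion_invariance(seed):
    rng = np.random.default_rng(seed)
    f = fx.make_collinear_chain(8, 0.5, D=50.0)
    g0 = gyration_components(f.frame, f.topology)
    shift = rng.uniform(-20, 20, 3)
    f.frame.positions += shift
    f.frame.wrap()
    g1 = gyration_components(f.frame, f.topology)
    # translation leaves all components unchanged (chains unwrapped first)
    for a, b in ((g0.rg_xx, g1.rg_xx), (g0.rg_yy, g1.rg_yy), (g0.rg_zz, g1.rg_zz)):
        assert b[0] == pytest.approx(a[0], abs=1e-9)


def test_gyration_chain_averaged_definition():
    # two chains of different extent: component is sqrt of mean of per-chain Rg^2
    topo = dm.build_lipid_topology(1, 2, 2)
    frame = dm.Frame.zeros(6, 30.0)
    frame.positions[:3, 2] = [0.0, 0.7, 1.4]
    frame.positions[3:, 2] = [5.0, 6.0, 7.0]
    frame.positions[:, 0] = 2.0
    g = gyration_components(frame, topo)
    rg2 = (fx.collinear_rg(3, 0.7) ** 2 + fx.collinear_rg(3, 1.0) ** 2) / 2
    assert g.rg_zz[0] == pytest.approx(np.sqrt(rg2), rel=1e-12)


def test_unwrap_chain_minimum_image():
    D = 10.0
    chain = np.array([[9.5, 0, 0], [0.2, 0, 0], [0.9, 0, 0]])
    un = unwrap_chain(chain, D)
    assert np.allclose(un[:, 0], [9.5, 10.2, 10.9])


# ---------------------------------------------------------------------------
# nanoparticle layering
# ---------------------------------------------------------------------------

def test_layering_conservation_and_planes():
    topo = dm.build_lipid_topology(1, 1, 1, n_nanoparticles=100)
    frame = dm.Frame.zeros(102, 10.0)
    rng = np.random.default_rng(0)
    frame.positions[:2] = rng.uniform(0, 10, (2, 3))
    frame.positions[2:] = rng.uniform(0, 10, (100, 3))
    frame.positions[2:52, 2] = 2.25  # two NP planes
    frame.positions[52:, 2] = 7.25
    out = nanoparticle_layering(frame, topo, bin_width=0.5)
    t, prof = out[0]
    n = prof.density_per_type["N"]
    total = n.sum() * 10 * 10 * 0.5
    assert total == pytest.approx(100, abs=1e-9)
    peaks = prof.bin_centers[n > 0]
    assert set(np.round(peaks, 2)) == {2.25, 7.25}


def test_layering_warns_without_nanoparticles(caplog):
    topo = dm.build_lipid_topology(1, 1, 2)
    frame = dm.Frame.zeros(4, 10.0)
    out = nanoparticle_layering(frame, topo, 0.5)
    assert out == []
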