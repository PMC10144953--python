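"""Synthetic configurations with analytically known observables.

Every builder returns the configuration together with an ``expectations``
dict of the analytic values the analysis code must reproduce, so each
analysis stage can be tested in seconds without running dynamics.  All
fixtures are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builder import init_velocities
from .forcefield import ForceFieldParams, TYPE_H, TYPE_T, flory_huggins_chi
from .state import Frame
from .topology import BoxSpec, Topology, build_lipid_topology

FIXTURE_KINDS = (
    "ideal_gas",
    "perfect_lamella",
    "perfect_cylinder",
    "oriented_chains",
    "collinear_chain",
    "two_phase_slab",
)


@dataclass
class Fixture:
    """A synthetic configuration plus its analytic expectations."""

    frame: Frame
    topology: Topology
    expectations: dict = field(default_factory=dict)
    forcefield: ForceFieldParams | None = None


def _free_bead_topology(n: int, bead_type: int = TYPE_H) -> Topology:
    """n unbonded single-bead "chains" of the given type (not
    nanoparticles, so type-specific analyses see lipid beads)."""
    return Topology(
        bead_types=np.full(n, bead_type, np.int8),
        chain_id=np.arange(n, dtype=np.int64),
        bonds=np.empty((0, 2), np.int64),
        angles=np.empty((0, 3), np.int64),
        n_head=1,
        n_tail=0,
        n_lipids=n,
        n_nanoparticles=0,
    )


def make_ideal_gas(rho: float, D: float, kT: float, seed: int) -> Fixture:
    """Non-interacting uniform gas: flat density rho everywhere, kinetic
    pressure rho*kT on each diagonal, zero tension."""
    if rho <= 0 or D <= 0 or kT < 0:
        raise ValueError("rho and D must be positive, kT non-negative")
    box = BoxSpec(D, rho)
    n = box.n_beads
    rng = np.random.default_rng(seed)
    topo = _free_bead_topology(n)
    frame = Frame.zeros(n, D)
    frame.positions[:] = rng.uniform(0.0, D, size=(n, 3))
    frame = init_velocities(frame, kT, seed + 1)
    return Fixture(
        frame,
        topo,
        expectations={
            "density": rho,
            "kinetic_pressure": rho * kT,
            "sigma_z": 0.0,
        },
    )


def make_oriented_chains(
    n_chains: int,
    polar_angle_dist,
    seed: int,
    n_head: int = 3,
    n_tail: int = 10,
    spacing: float = 0.7,
    D: float = 30.0,
) -> Fixture:
    """Rigid straight chains whose polar angles theta (to the z-axis) are
    drawn from ``polar_angle_dist``.

    ``polar_angle_dist`` may be a scalar angle (delta distribution), the
    string "isotropic" (directions uniform on the sphere), or a callable
    ``f(rng, n) -> angles``.  Azimuths are uniform.  The analytic
    expectation is <P2(cos theta)> of the sampled angles.
    """
    rng = np.random.default_rng(seed)
    if polar_angle_dist == "isotropic":
        cos_t = rng.uniform(-1.0, 1.0, size=n_chains)
        theta = np.arccos(cos_t)
    elif np.isscalar(polar_angle_dist):
        theta = np.full(n_chains, float(polar_angle_dist))
    else:
        theta = np.asarray(polar_angle_dist(rng, n_chains), dtype=float)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_chains)
    dirs = np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    m = n_head + n_tail
    topo = build_lipid_topology(n_head, n_tail, n_chains)
    starts = rng.uniform(0.0, D, size=(n_chains, 3))
    k = np.arange(m)[None, :, None]
    pos = starts[:, None, :] + k * spacing * dirs[:, None, :]
    frame = Frame.zeros(n_chains * m, D)
    frame.positions[:] = pos.reshape(-1, 3)
    frame.wrap()
    p2 = float(np.mean(1.5 * np.cos(theta) ** 2 - 0.5))
    return Fixture(frame, topo, expectations={"order_parameter": p2})


def collinear_rg(n_beads: int, spacing: float) -> float:
    """Closed-form gyration radius of n equally spaced collinear beads:
    sqrt(spacing^2 (n^2 - 1) / 12)."""
    return float(np.sqrt(spacing**2 * (n_beads**2 - 1) / 12.0))


def make_collinear_chain(
    n_beads: int = 13, spacing: float = 0.7, axis=(0.0, 0.0, 1.0), D: float = 30.0
) -> Fixture:
    """A single straight chain along ``axis``; Rg along the axis has the
    equally-spaced closed form, transverse components are zero."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    n_head = min(3, n_beads - 1) if n_beads > 1 else 1
    n_tail = n_beads - n_head
    if n_tail == 0:
        topo = _free_bead_topology(1)
    else:
        topo = build_lipid_topology(n_head, n_tail, 1)
    start = np.full(3, D / 4.0)
    pos = start[None, :] + np.arange(n_beads)[:, None] * spacing * axis[None, :]
    frame = Frame.zeros(n_beads, D)
    frame.positions[:] = pos
    frame.wrap()
    return Fixture(
        frame,
        topo,
        expectations={
            "rg_axis": collinear_rg(n_beads, spacing),
            "rg_transverse": 0.0,
        },
    )


def make_perfect_lamella(
    period: float,
    n_head: int = 3,
    n_tail: int = 10,
    D: float = 30.0,
    spacing: float = 0.7,
    chains_per_leaflet: int = 64,
    seed: int = 0,
) -> Fixture:
    """Ideal lamellar stack: extended chains along +/-z in alternating
    leaflets, heads at the period boundaries, square-wave density.

    ``period`` must divide D.  Expectations: H bead fraction, per-chain
    Rg along z (collinear closed form), order parameter 1 in every
    populated bin, H-slab centre positions.
    """
    n_rep = D / period
    if abs(n_rep - round(n_rep)) > 1e-9:
        raise ValueError("period must divide the box length")
    n_rep = int(round(n_rep))
    rng = np.random.default_rng(seed)
    m = n_head + n_tail
    n_chains = 2 * n_rep * chains_per_leaflet
    topo = build_lipid_topology(n_head, n_tail, n_chains)
    pos = np.empty((n_chains * m, 3))
    k = np.arange(m)
    c = 0
    for r in range(n_rep):
        for leaflet in range(2):
            for _ in range(chains_per_leaflet):
                x, y = rng.uniform(0.0, D, size=2)
                if leaflet == 0:
                    z = r * period + (k + 0.5) * spacing
                else:
                    z = (r + 1) * period - (k + 0.5) * spacing
                sl = slice(c * m, (c + 1) * m)
                pos[sl, 0] = x
                pos[sl, 1] = y
                pos[sl, 2] = z
                c += 1
    frame = Frame.zeros(n_chains * m, D)
    frame.positions[:] = pos
    frame.wrap()
    return Fixture(
        frame,
        topo,
        expectations={
            "head_fraction": n_head / m,
            "rg_zz": collinear_rg(m, spacing),
            "rg_xx": 0.0,
            "order_parameter": 1.0,
            "h_slab_centers": [r * period % D for r in range(n_rep)],
            "period": period,
        },
    )


def make_perfect_cylinder(
    radius: float,
    n_beads: int = 2000,
    D: float = 30.0,
    axis_point=(15.0, 15.0, 0.0),
    seed: int = 0,
) -> Fixture:
    """Beads uniform inside one z-aligned cylinder of known radius: the
    radial density is flat inside and exactly zero beyond the radius."""
    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.uniform(size=n_beads))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_beads)
    z = rng.uniform(0.0, D, size=n_beads)
    topo = _free_bead_topology(n_beads)
    frame = Frame.zeros(n_beads, D)
    frame.positions[:, 0] = axis_point[0] + r * np.cos(phi)
    frame.positions[:, 1] = axis_point[1] + r * np.sin(phi)
    frame.positions[:, 2] = z
    frame.wrap()
    density = n_beads / (np.pi * radius**2 * D)
    return Fixture(
        frame,
        topo,
        expectations={"radius": radius, "inner_density": density},
    )


def make_two_phase_slab(
    a_like: float,
    a_unlike: float,
    D: float = 10.0,
    rho: float = 3.0,
    seed: int = 0,
    relax_steps: int = 2000,
    dt: float = 0.01,
) -> Fixture:
    """Two immiscible bead species filling half-boxes stacked along z.

    After a brief thermostatted relaxation (to populate velocity
    statistics and sharpen the interfaces) the tension profile shows
    peaks at the two z-interfaces and sigma_z > 0 for a_unlike > a_like.
    Expectation: the Flory-Huggins estimate chi = 0.286 (a_unlike - a_like).
    """
    if a_unlike < a_like:
        raise ValueError("a_unlike must be >= a_like")
    from .engine import RunConfig, run  # local import avoids cycle at import time

    box = BoxSpec(D, rho)
    n = box.n_beads
    n_a = n // 2
    rng = np.random.default_rng(seed)
    types = np.concatenate(
        [np.full(n_a, TYPE_H, np.int8), np.full(n - n_a, TYPE_T, np.int8)]
    )
    topo = Topology(
        bead_types=types,
        chain_id=np.arange(n, dtype=np.int64),
        bonds=np.empty((0, 2), np.int64),
        angles=np.empty((0, 3), np.int64),
        n_head=1,
        n_tail=0,
        n_lipids=n,
        n_nanoparticles=0,
    )
    pos = np.empty((n, 3))
    pos[:n_a, 0:2] = rng.uniform(0.0, D, size=(n_a, 2))
    pos[:n_a, 2] = rng.uniform(0.0, D / 2.0, size=n_a)
    pos[n_a:, 0:2] = rng.uniform(0.0, D, size=(n - n_a, 2))
    pos[n_a:, 2] = rng.uniform(D / 2.0, D, size=n - n_a)
    frame = Frame.zeros(n, D)
    frame.positions[:] = pos
    frame = init_velocities(frame, 1.0, seed + 1)

    amat = np.full((3, 3), a_unlike)
    np.fill_diagonal(amat, a_like)
    ff = ForceFieldParams(interaction_matrix=amat)
    if relax_steps > 0:
        cfg = RunConfig(dt=dt, n_steps=relax_steps, seed=seed, sample_every=max(1, relax_steps))
        traj, _ = run(frame, topo, ff, cfg)
        frame = traj.frames[-1]
    return Fixture(
        frame,
        topo,
        expectations={
            "chi": flory_huggins_chi(a_unlike, a_like),
            "interfaces_z": [D / 2.0, 0.0],
            "sigma_positive": a_unlike > a_like,
        },
        forcefield=ff,
    )
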