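"""Initial configurations: random melts and preassembled mesophases.

Chains are laid down as random walks (random start) or as extended rods
(preassembled lamellar / hexagonal geometry); nanoparticles are always
placed uniformly at random, matching the protocol of seeding randomly
distributed particles into a chosen initial lipid structure.  All builders
are deterministic per seed.
"""

from __future__ import annotations

import numpy as np

from .state import Frame
from .topology import BoxSpec, Topology

PHASES = ("lamellar", "hexagonal")


def _check_counts(topology: Topology, box: BoxSpec) -> None:
    # Allow one lipid chain of slack against rho*D^3 rounding.
    expected = box.n_beads
    if abs(topology.n_beads - expected) > topology.beads_per_lipid:
        raise ValueError(
            f"bead count {topology.n_beads} inconsistent with density: "
            f"rho*D^3 = {expected} (tolerance one chain)"
        )


def place_random_melt(topology: Topology, box: BoxSpec, seed: int, bond_length: float = 0.7) -> Frame:
    """Random-walk melt: each chain starts at a uniform point and grows by
    steps of length ``bond_length`` in uniform random directions; beads are
    wrapped into the box.  Nanoparticles are uniform in the box."""
    _check_counts(topology, box)
    rng = np.random.default_rng(seed)
    D = box.length
    m = topology.beads_per_lipid
    pos = np.empty((topology.n_beads, 3))
    for c in range(topology.n_lipids):
        sl = topology.chain_slice(c)
        steps = rng.normal(size=(m - 1, 3))
        steps *= bond_length / np.linalg.norm(steps, axis=1)[:, None]
        chain = np.empty((m, 3))
        chain[0] = rng.uniform(0.0, D, size=3)
        chain[1:] = chain[0] + np.cumsum(steps, axis=0)
        pos[sl] = chain
    if topology.n_nanoparticles:
        pos[topology.n_lipids * m:] = rng.uniform(0.0, D, size=(topology.n_nanoparticles, 3))
    frame = Frame.zeros(topology.n_beads, D)
    frame.positions[:] = pos
    frame.wrap()
    return frame


def lamellar_period(box_length: float, beads_per_lipid: int, bond_length: float = 0.7) -> float:
    """Period of the preassembled lamellar stack: D / n_repeats with
    n_repeats the integer whose period is closest to one bilayer of fully
    extended chains, 2 * (NH + NT) * rs."""
    ideal = 2.0 * beads_per_lipid * bond_length
    n_repeats = max(1, round(box_length / ideal))
    return box_length / n_repeats


def place_preassembled(
    topology: Topology, box: BoxSpec, phase: str, seed: int, bond_length: float = 0.7
) -> Frame:
    """Preassembled mesophase start.

    lamellar
        Alternating H/T slabs normal to z.  Each period holds two leaflets
        of extended chains (heads at the period boundaries, tails meeting
        mid-period).  The bead spacing is the half-period divided by the
        chain length, clamped to within 15% of ``bond_length`` so freshly
        built bonds stay near their equilibrium length.
    hexagonal
        Head-bead cylinders along z on an offset (triangular-like) lattice
        in the x-y plane; chains point radially outward, tails filling the
        matrix.

    Nanoparticles are placed uniformly at random in both phases.
    """
    if phase not in PHASES:
        raise ValueError(f"unsupported phase {phase!r}; expected one of {PHASES}")
    _check_counts(topology, box)
    rng = np.random.default_rng(seed)
    D = box.length
    m = topology.beads_per_lipid
    pos = np.empty((topology.n_beads, 3))

    if phase == "lamellar":
        period = lamellar_period(D, m, bond_length)
        spacing = np.clip(period / (2.0 * m), 0.85 * bond_length, 1.15 * bond_length)
        n_repeats = int(round(D / period))
        n_chains = topology.n_lipids
        # Chains assigned round-robin to (repeat, leaflet) cells.
        cells = 2 * n_repeats
        k = np.arange(m)
        for c in range(n_chains):
            cell = c % cells
            repeat, leaflet = divmod(cell, 2)
            x, y = rng.uniform(0.0, D, size=2)
            jitter = rng.uniform(-0.25, 0.25) * spacing
            if leaflet == 0:  # head at the lower period boundary, pointing up
                z = repeat * period + (k + 0.5) * spacing + jitter
            else:  # head at the upper boundary, pointing down
                z = (repeat + 1) * period - (k + 0.5) * spacing + jitter
            sl = topology.chain_slice(c)
            pos[sl, 0] = x
            pos[sl, 1] = y
            pos[sl, 2] = z
    else:  # hexagonal
        # Offset lattice of cylinder axes: 2 columns x 2 rows, odd rows
        # shifted by half a column - the periodic image of a triangular
        # packing squeezed into a cubic box.
        axes = []
        for j in range(2):
            for i in range(2):
                axes.append(((i + 0.5 * (j % 2)) * D / 2.0 + D / 8.0, j * D / 2.0 + D / 4.0))
        axes = np.asarray(axes)
        k = np.arange(m)
        for c in range(topology.n_lipids):
            ax, ay = axes[c % len(axes)]
            phi = rng.uniform(0.0, 2.0 * np.pi)
            z = rng.uniform(0.0, D)
            # head-most bead innermost; radial spacing = bond_length
            r = (k + 0.5) * bond_length
            sl = topology.chain_slice(c)
            pos[sl, 0] = ax + r * np.cos(phi)
            pos[sl, 1] = ay + r * np.sin(phi)
            pos[sl, 2] = z

    if topology.n_nanoparticles:
        pos[topology.n_lipids * m:] = rng.uniform(0.0, D, size=(topology.n_nanoparticles, 3))

    frame = Frame.zeros(topology.n_beads, D)
    frame.positions[:] = pos
    frame.wrap()
    return frame


def init_velocities(frame: Frame, kT: float, seed: int, mass: float = 1.0) -> Frame:
    """Draw Maxwell-Boltzmann velocities at temperature kT and remove the
    net momentum.  kT = 0 gives an athermal (all-zero) start."""
    if kT < 0:
        raise ValueError("kT must be non-negative")
    out = frame.copy()
    if kT == 0:
        out.velocities[:] = 0.0
        return out
    rng = np.random.default_rng(seed)
    v = rng.normal(scale=np.sqrt(kT / mass), size=(frame.n_beads, 3))
    v -= v.mean(axis=0)
    out.velocities[:] = v
    return out
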