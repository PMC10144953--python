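"""Bead topologies for lipid chains and nanoparticles.

A lipid is a single linear chain of NH head (H) beads followed by NT tail
(T) beads, bonded consecutively.  Nanoparticles are single unbonded N
beads.  Angle triples are placed on consecutive head beads only: the head
group is the rigid part of the molecule, the tail stays fully flexible
(an ``angle_scheme="all"`` option stiffens every triple instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forcefield import TYPE_H, TYPE_N, TYPE_T


@dataclass
class Topology:
    """Bead types, chain membership and bonded terms of one system.

    ``chain_id`` is -1 for nanoparticles (chainless).  ``bonds`` is an
    (n_bonds, 2) int array of bead indices, ``angles`` an (n_angles, 3)
    array of consecutive triples (center bead second).
    """

    bead_types: np.ndarray
    chain_id: np.ndarray
    bonds: np.ndarray
    angles: np.ndarray
    n_head: int
    n_tail: int
    n_lipids: int
    n_nanoparticles: int

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)

    @property
    def beads_per_lipid(self) -> int:
        return self.n_head + self.n_tail

    def chain_slice(self, chain: int) -> slice:
        """Index slice of the beads of one lipid chain (chains are stored
        contiguously, nanoparticles after all chains)."""
        m = self.beads_per_lipid
        return slice(chain * m, (chain + 1) * m)

    def validate(self) -> None:
        n = self.n_beads
        if n != self.n_lipids * self.beads_per_lipid + self.n_nanoparticles:
            raise ValueError("bead count inconsistent with chain/nanoparticle counts")
        if len(self.chain_id) != n:
            raise ValueError("chain_id length mismatch")
        if self.bonds.size and (
            self.bonds.min() < 0 or self.bonds.max() >= n
        ):
            raise ValueError("bond indices out of range")
        if (self.bead_types[self.chain_id < 0] != TYPE_N).any():
            raise ValueError("chainless beads must be nanoparticles")


def build_lipid_topology(
    n_head: int,
    n_tail: int,
    n_lipids: int,
    n_nanoparticles: int = 0,
    angle_scheme: str = "head",
) -> Topology:
    """Construct the topology of ``n_lipids`` identical lipid chains plus
    ``n_nanoparticles`` free nanoparticle beads.

    Each chain is H * n_head followed by T * n_tail; consecutive beads are
    bonded, so each chain carries ``n_head + n_tail - 1`` bonds.  With the
    default ``angle_scheme="head"`` an angle triple is placed on every set
    of three consecutive head beads (``n_head - 2`` per chain, none if
    ``n_head < 3``); ``angle_scheme="all"`` places one on every consecutive
    triple of the chain.

    Examples
    --------
    >>> topo = build_lipid_topology(3, 10, 1)
    >>> topo.n_beads, len(topo.bonds), len(topo.angles)
    (13, 12, 1)
    """
    if n_head < 1 or n_tail < 1 or n_lipids < 1:
        raise ValueError("n_head, n_tail and n_lipids must all be >= 1")
    if n_nanoparticles < 0:
        raise ValueError("n_nanoparticles must be >= 0")
    if angle_scheme not in ("head", "all"):
        raise ValueError(f"unknown angle_scheme {angle_scheme!r}")

    m = n_head + n_tail
    chain_types = np.array([TYPE_H] * n_head + [TYPE_T] * n_tail, dtype=np.int8)
    bead_types = np.concatenate(
        [np.tile(chain_types, n_lipids), np.full(n_nanoparticles, TYPE_N, np.int8)]
    )
    chain_id = np.concatenate(
        [np.repeat(np.arange(n_lipids), m), np.full(n_nanoparticles, -1)]
    ).astype(np.int64)

    offsets = np.arange(n_lipids)[:, None] * m
    local_bonds = np.column_stack([np.arange(m - 1), np.arange(1, m)])
    bonds = (offsets[:, :, None] + local_bonds[None, :, :]).reshape(-1, 2)

    if angle_scheme == "head":
        n_triples = max(n_head - 2, 0)
    else:
        n_triples = max(m - 2, 0)
    if n_triples:
        local_angles = np.column_stack(
            [np.arange(n_triples), np.arange(1, n_triples + 1), np.arange(2, n_triples + 2)]
        )
        angles = (offsets[:, :, None] + local_angles[None, :, :]).reshape(-1, 3)
    else:
        angles = np.empty((0, 3), dtype=np.int64)

    topo = Topology(
        bead_types=bead_types,
        chain_id=chain_id,
        bonds=bonds.astype(np.int64),
        angles=angles.astype(np.int64),
        n_head=n_head,
        n_tail=n_tail,
        n_lipids=n_lipids,
        n_nanoparticles=n_nanoparticles,
    )
    topo.validate()
    return topo


def nanoparticle_count(phi_np: float, box_length: float) -> int:
    """Number of nanoparticles at concentration phi_NP = N_NP / D^3."""
    if phi_np < 0:
        raise ValueError("nanoparticle concentration must be non-negative")
    if box_length <= 0:
        raise ValueError("box length must be positive")
    return int(round(phi_np * box_length**3))


def lipid_count(
    rho: float, box_length: float, beads_per_lipid: int, n_nanoparticles: int = 0
) -> int:
    """Number of lipids filling the box to bead density rho, after the
    nanoparticles have displaced their share of beads."""
    total = round(rho * box_length**3)
    n = int(round((total - n_nanoparticles) / beads_per_lipid))
    if n < 1:
        raise ValueError("box too small or nanoparticle load too high: no lipids fit")
    return n


@dataclass
class BoxSpec:
    """Cubic periodic box of side ``length`` (rc) at bead density
    ``density`` (beads/rc^3).  rho = 3 is the standard DPD convention
    matching the a_ii = 25 repulsion parametrisation."""

    length: float
    density: float = 3.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("box length must be positive")
        if self.density <= 0:
            raise ValueError("bead density must be positive")

    @property
    def volume(self) -> float:
        return self.length**3

    @property
    def n_beads(self) -> int:
        return int(round(self.density * self.volume))
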