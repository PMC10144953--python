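"""Structural observables: density profiles, orientational order and
chain-shape (gyration) measures.

Conventions
-----------
* Axial profiles are histograms along z normalised by the bin volume
  D * D * dz, one curve per bead type, in beads/rc^3.
* The chain direction entering the orientational order parameter
  <P2(cos theta)> = <(3 cos^2 theta - 1) / 2> is the unit vector from the
  first head bead to the last tail bead of the unwrapped chain (the
  "head-segment" alternative uses the head group only).  A chain is
  assigned to the z-bin of its first head bead.
* Gyration components: per chain, the diagonal second moment of the
  unwrapped bead positions about the chain's centre of mass; the reported
  Rg_aa is the square root of the chain-averaged Rg_aa^2.  Chains are
  unwrapped bond-by-bond (minimum image per bond) before any centering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .forcefield import TYPE_NAMES
from .state import Frame, Trajectory
from .topology import Topology

log = logging.getLogger(__name__)


@dataclass
class AxialProfile:
    """Per-type bead density along z: densities in beads/rc^3 per bin."""

    bin_edges: np.ndarray
    density_per_type: dict

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class RadialProfile:
    """Per-type bead density in cylindrical annuli about an axis."""

    bin_edges: np.ndarray
    density_per_type: dict

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class OrderProfile:
    """<P2> per z-bin; empty bins carry NaN, not zero."""

    bin_centers: np.ndarray
    p2: np.ndarray
    n_chains: np.ndarray


@dataclass
class GyrationSeries:
    """Chain-averaged gyration components per sampled time (rc)."""

    times: np.ndarray
    rg_xx: np.ndarray
    rg_yy: np.ndarray
    rg_zz: np.ndarray

    @property
    def rg(self) -> np.ndarray:
        return np.sqrt(self.rg_xx**2 + self.rg_yy**2 + self.rg_zz**2)


def _axial_edges(box_length: float, bin_width: float) -> np.ndarray:
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = max(1, int(round(box_length / bin_width)))
    return np.linspace(0.0, box_length, n_bins + 1)


def axial_density(frame: Frame, topology: Topology, bin_width: float = 0.25) -> AxialProfile:
    """Per-type density along z, normalised by the bin volume D*D*dz."""
    D = frame.box_length
    edges = _axial_edges(D, bin_width)
    vol = D * D * np.diff(edges)
    z = frame.positions[:, 2] % D
    density = {}
    for t, name in enumerate(TYPE_NAMES):
        mask = topology.bead_types == t
        if not mask.any():
            continue
        counts, _ = np.histogram(z[mask], bins=edges)
        density[name] = counts / vol
    return AxialProfile(edges, density)


def radial_density(
    frame: Frame,
    topology: Topology,
    axis_point: np.ndarray,
    axis_dir: np.ndarray,
    bin_width: float = 0.25,
    r_max: float | None = None,
) -> RadialProfile:
    """Per-type density in annuli about a cylinder axis, using
    minimum-image perpendicular distances."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    axis_dir = np.asarray(axis_dir, dtype=float)
    norm = np.linalg.norm(axis_dir)
    if norm < 1e-12:
        raise ValueError("degenerate cylinder axis")
    e = axis_dir / norm
    D = frame.box_length
    if r_max is None:
        r_max = D / 2.0
    d = frame.positions - np.asarray(axis_point, dtype=float)
    d -= D * np.rint(d / D)
    perp = d - np.outer(d @ e, e)
    r = np.linalg.norm(perp, axis=1)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    # annulus volume = pi (r2^2 - r1^2) * height; height = axis extent = D
    vol = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * D
    density = {}
    for t, name in enumerate(TYPE_NAMES):
        mask = topology.bead_types == t
        if not mask.any():
            continue
        counts, _ = np.histogram(r[mask], bins=edges)
        density[name] = counts / vol
    return RadialProfile(edges, density)


def unwrap_chain(positions: np.ndarray, box_length: float) -> np.ndarray:
    """Unwrap one chain bond-by-bond: each bead is placed at the minimum
    image relative to its predecessor."""
    out = positions.copy()
    d = np.diff(positions, axis=0)
    d -= box_length * np.rint(d / box_length)
    out[1:] = out[0] + np.cumsum(d, axis=0)
    return out


def chain_direction(chain_positions: np.ndarray, box_length: float | None = None) -> np.ndarray:
    """Unit vector from the first to the last bead of a chain, unwrapped
    across periodic boundaries when ``box_length`` is given."""
    p = np.asarray(chain_positions, dtype=float)
    if len(p) < 2:
        raise ValueError("chain direction needs at least two beads")
    if box_length is not None:
        p = unwrap_chain(p, box_length)
    v = p[-1] - p[0]
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("coincident chain endpoints: direction undefined")
    return v / n


def _chain_matrix(frame: Frame, topology: Topology) -> np.ndarray:
    m = topology.beads_per_lipid
    nl = topology.n_lipids
    return frame.positions[: nl * m].reshape(nl, m, 3)


def _unwrap_chains(chains: np.ndarray, box_length: float) -> np.ndarray:
    d = np.diff(chains, axis=1)
    d -= box_length * np.rint(d / box_length)
    out = chains.copy()
    out[:, 1:, :] = out[:, :1, :] + np.cumsum(d, axis=1)
    return out


def order_parameter(
    frames,
    topology: Topology,
    bin_width: float = 0.25,
    direction_mode: str = "endtoend",
) -> OrderProfile:
    """z-resolved nematic order parameter <P2(cos theta)> of the lipid
    chains relative to the z-axis, ensemble-averaged over frames.

    theta is the angle between the chain direction and z.  A chain
    contributes to the bin of its first head bead's (wrapped) z.  Bins
    never visited hold NaN.
    """
    frames = _as_frames(frames)
    if not frames:
        raise ValueError("need at least one frame")
    D = frames[0].box_length
    edges = _axial_edges(D, bin_width)
    nb = len(edges) - 1
    sums = np.zeros(nb)
    counts = np.zeros(nb, dtype=np.int64)
    if direction_mode == "endtoend":
        last = topology.beads_per_lipid - 1
    elif direction_mode == "head":
        last = topology.n_head - 1
        if last < 1:
            raise ValueError("head-segment direction needs at least two head beads")
    else:
        raise ValueError(f"unknown direction_mode {direction_mode!r}")
    skipped = 0
    for frame in frames:
        chains = _unwrap_chains(_chain_matrix(frame, topology), D)
        v = chains[:, last, :] - chains[:, 0, :]
        norm = np.linalg.norm(v, axis=1)
        ok = norm > 1e-12
        skipped += int((~ok).sum())
        cos = v[ok, 2] / norm[ok]
        p2 = 1.5 * cos**2 - 0.5
        zref = frame.positions[np.arange(topology.n_lipids) * topology.beads_per_lipid, 2][ok] % D
        idx = np.minimum((zref / (D / nb)).astype(np.int64), nb - 1)
        np.add.at(sums, idx, p2)
        np.add.at(counts, idx, 1)
    if skipped:
        log.warning("%d chain(s) with coincident endpoints skipped", skipped)
    p2 = np.full(nb, np.nan)
    populated = counts > 0
    p2[populated] = sums[populated] / counts[populated]
    return OrderProfile(0.5 * (edges[:-1] + edges[1:]), p2, counts)


def order_parameter_scalar(directions: np.ndarray) -> float:
    """<P2> of a set of (unit) direction vectors against the z-axis."""
    d = np.asarray(directions, dtype=float)
    cos = d[:, 2] / np.linalg.norm(d, axis=1)
    return float(np.mean(1.5 * cos**2 - 0.5))


def gyration_components(frames, topology: Topology) -> GyrationSeries:
    """Diagonal gyration-tensor components, chain-averaged, per frame.

    Per chain: Rg_aa^2 = (1/n_beads) sum_i (r_i,a - r_cm,a)^2 over the
    unwrapped beads; the series reports sqrt(<Rg_aa^2>_chains).
    """
    frames = _as_frames(frames)
    times, comps = [], []
    for frame in frames:
        chains = _unwrap_chains(_chain_matrix(frame, topology), frame.box_length)
        cm = chains.mean(axis=1, keepdims=True)
        d = chains - cm
        rg2 = (d**2).mean(axis=1)  # (n_chains, 3)
        comps.append(np.sqrt(rg2.mean(axis=0)))
        times.append(frame.time)
    comps = np.array(comps) if comps else np.zeros((0, 3))
    return GyrationSeries(
        np.array(times), comps[:, 0], comps[:, 1], comps[:, 2]
    )


def nanoparticle_layering(
    frames, topology: Topology, bin_width: float = 0.25, times=None
) -> list:
    """Axial nanoparticle density profile at each requested time (default:
    every frame).  Returns an empty list with a warning when the system
    has no nanoparticles."""
    frames = _as_frames(frames)
    if topology.n_nanoparticles == 0:
        log.warning("no nanoparticles in this system: empty layering result")
        return []
    if times is not None:
        wanted = []
        remaining = list(times)
        for f in frames:
            if remaining and f.time >= remaining[0] - 1e-9:
                wanted.append(f)
                remaining.pop(0)
        frames = wanted
    out = []
    for frame in frames:
        profile = axial_density(frame, topology, bin_width)
        out.append((frame.time, profile))
    return out


def _as_frames(frames):
    if isinstance(frames, Frame):
        return [frames]
    if isinstance(frames, Trajectory):
        return list(frames.frames)
    return list(frames)
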