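"""Pressure tensor and Irving-Kirkwood interfacial tension.

The pressure tensor is the kinetic term sum_i m v_ia v_ib / V plus the
pair virial sum_{i<j} F_ij,a d_ij,b / V, where d_ij is the minimum-image
separation.  By default the dissipative and random pair forces enter the
instantaneous virial together with the conservative and bonded terms (a
conservative-only option is provided; conventions differ).  The
three-body angle term is decomposed onto its two bond vectors, which is
exact because the three angle forces sum to zero.

The z-resolved tension uses the Irving-Kirkwood line-segment partition:
each pair's diagonal virial is spread over the z-slabs crossed by the
i-j segment in proportion to the path length inside each slab, and the
kinetic part is binned by bead position.  The slab-width-weighted mean of
the per-slab tension then equals the global sigma_z identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .engine import compute_forces, _kinetic_tensor
from .forcefield import ForceFieldParams
from .observables import AxialProfile, _as_frames
from .state import Frame, Trajectory
from .topology import Topology


@dataclass
class PressureTensor:
    """3x3 pressure tensor in kBT/rc^3, with its kinetic/virial split."""

    components: np.ndarray
    kinetic_part: np.ndarray
    virial_part: np.ndarray

    @property
    def pxx(self) -> float:
        return float(self.components[0, 0])

    @property
    def pyy(self) -> float:
        return float(self.components[1, 1])

    @property
    def pzz(self) -> float:
        return float(self.components[2, 2])


@dataclass
class TensionProfile:
    """Per-slab tension sigma_z(z) = pzz - (pxx + pyy)/2 in kBT/rc^3."""

    slab_centers: np.ndarray
    sigma_z: np.ndarray
    slab_width: float
    global_sigma_z: float


@dataclass
class TensionSeries:
    """Global sigma_z per sampled frame, with a running mean."""

    times: np.ndarray
    sigma_z: np.ndarray
    running_mean: np.ndarray

    def plateau_mean(self, fraction: float = 1.0 / 3.0) -> float:
        """Mean over the final ``fraction`` of the series (the equilibrium
        plateau window; the final third by default)."""
        n = max(1, int(round(len(self.sigma_z) * fraction)))
        return float(np.mean(self.sigma_z[-n:]))


@dataclass
class PeakSummary:
    """Large/small tension peaks and the head/tail domain sizes derived
    from consecutive large-peak spacings (all lengths in rc)."""

    large_peak_positions: np.ndarray
    large_peak_mean: float
    small_peak_positions: np.ndarray
    small_peak_mean: float
    head_domain_size: float
    tail_domain_size: float


def pressure_tensor(
    frame: Frame,
    topology: Topology,
    ff: ForceFieldParams,
    dt: float = 0.01,
    seed: int = 0,
    step_index: int = 0,
    conservative_only: bool = False,
) -> PressureTensor:
    """Instantaneous pressure tensor of one frame.

    With ``conservative_only`` the dissipative and random pair forces are
    excluded from the virial.  ``seed``/``step_index`` key the random-force
    noise so the virial matches a specific engine force evaluation.
    """
    V = frame.box_length**3
    _, _, virial = compute_forces(
        frame, topology, ff, dt=dt, seed=seed, step_index=step_index,
        include_dissipative=not conservative_only,
        include_random=not conservative_only,
    )
    kin = _kinetic_tensor(frame, ff.mass) / V
    vir = virial / V
    return PressureTensor(kin + vir, kin, vir)


def pressure_from_parts(kin: np.ndarray, vir: np.ndarray) -> PressureTensor:
    return PressureTensor(kin + vir, kin, vir)


def tension_from_tensor(p: PressureTensor) -> float:
    return p.pzz - 0.5 * (p.pxx + p.pyy)


def tension_global(
    frame: Frame,
    topology: Topology,
    ff: ForceFieldParams,
    **kwargs,
) -> float:
    """Global interfacial tension sigma_z = pzz - (pxx + pyy)/2."""
    return tension_from_tensor(pressure_tensor(frame, topology, ff, **kwargs))


def tension_profile(
    frames,
    topology: Topology,
    ff: ForceFieldParams,
    slab_width: float = 0.25,
    method: str = "ik",
    dt: float = 0.01,
    seed: int = 0,
    conservative_only: bool = False,
) -> TensionProfile:
    """Time-averaged z-resolved tension profile.

    ``method`` "ik" uses the Irving-Kirkwood segment partition; "midpoint"
    assigns each pair's virial to the slab of the segment midpoint (cheaper,
    still integrates exactly to the global value).
    """
    if slab_width <= 0:
        raise ValueError("slab_width must be positive")
    frames = _as_frames(frames)
    if not frames:
        raise ValueError("need at least one frame")
    D = frames[0].box_length
    n_slabs = max(1, int(round(D / slab_width)))
    if D / n_slabs < 1e-6:
        raise ValueError("slab thinner than numerical resolution")
    w = D / n_slabs
    V_slab = D * D * w
    acc = np.zeros((n_slabs, 3))
    for k, frame in enumerate(frames):
        _, _, _, slab_vir = compute_forces(
            frame, topology, ff, dt=dt, seed=seed, step_index=k,
            include_dissipative=not conservative_only,
            include_random=not conservative_only,
            slab_profile=method, n_slabs=n_slabs,
        )
        kin = np.zeros((n_slabs, 3))
        z = frame.positions[:, 2] % D
        idx = np.minimum((z / w).astype(np.int64), n_slabs - 1)
        np.add.at(kin, idx, ff.mass * frame.velocities**2)
        acc += (slab_vir + kin) / V_slab
    acc /= len(frames)
    sigma = acc[:, 2] - 0.5 * (acc[:, 0] + acc[:, 1])
    centers = (np.arange(n_slabs) + 0.5) * w
    global_sigma = float(np.sum(sigma * w) / D)
    return TensionProfile(centers, sigma, w, global_sigma)


def tension_series(
    trajectory: Trajectory,
    topology: Topology,
    ff: ForceFieldParams,
    window: int = 10,
    **kwargs,
) -> TensionSeries:
    """Global sigma_z for every sampled frame of a trajectory.

    Uses the engine-recorded pressure tensors when present (they include
    the exact random/dissipative virial of the run); otherwise recomputes
    from the frames.
    """
    if isinstance(trajectory, Trajectory) and trajectory.pressure_tensors:
        times = trajectory.times
        sig = np.array(
            [
                tension_from_tensor(pressure_from_parts(p[0], p[1]))
                for p in trajectory.pressure_tensors
            ]
        )
    else:
        frames = _as_frames(trajectory)
        times = np.array([f.time for f in frames])
        sig = np.array(
            [
                tension_global(f, topology, ff, step_index=k, **kwargs)
                for k, f in enumerate(frames)
            ]
        )
    if window < 1:
        raise ValueError("running-mean window must be >= 1")
    kernel = np.ones(min(window, len(sig))) / min(window, len(sig))
    running = np.convolve(sig, kernel, mode="same") if len(sig) else sig.copy()
    return TensionSeries(times, sig, running)


def peak_and_domain_summary(
    profile: TensionProfile, density: AxialProfile
) -> PeakSummary:
    """Classify tension peaks as large/small and derive domain sizes.

    Local maxima of the tension profile are split into "large" and
    "small" by thresholding at the midpoint between the means of the two
    height clusters (2-means on peak heights).  Large peaks sit at the
    head/tail interfaces; the spacing between consecutive large peaks is
    assigned to the head or tail domain according to the dominant bead
    type between them, and the mean spacing per type is the domain size.
    """
    sig = profile.sigma_z
    pos = profile.slab_centers
    idx, _ = find_peaks(sig)
    # periodic: check the wrap-around neighbours too
    n = len(sig)
    for i in (0, n - 1):
        if sig[i] > sig[(i - 1) % n] and sig[i] > sig[(i + 1) % n] and i not in idx:
            idx = np.sort(np.append(idx, i))
    if len(idx) < 2:
        raise ValueError("fewer than two peaks: cannot compute domain sizes")
    heights = sig[idx]
    large_mask = _split_large_small(heights)
    large_idx = idx[large_mask]
    small_idx = idx[~large_mask]
    if len(large_idx) < 2:
        raise ValueError("fewer than two large peaks: cannot compute domain sizes")
    large_pos = pos[large_idx]
    D = pos[-1] + profile.slab_width / 2.0

    head = density.density_per_type.get("H")
    tail = density.density_per_type.get("T")
    if head is None or tail is None:
        raise ValueError("density profile must carry H and T curves")
    dcenters = 0.5 * (density.bin_edges[:-1] + density.bin_edges[1:])

    head_gaps, tail_gaps = [], []
    for a, b in zip(large_pos, np.append(large_pos[1:], large_pos[0] + D)):
        mid_lo, mid_hi = a, b
        mask = (dcenters > mid_lo) & (dcenters < mid_hi % D) if mid_hi <= D else (
            (dcenters > mid_lo) | (dcenters < mid_hi - D)
        )
        if not mask.any():
            continue
        gap = b - a
        if head[mask].sum() >= tail[mask].sum():
            head_gaps.append(gap)
        else:
            tail_gaps.append(gap)
    return PeakSummary(
        large_peak_positions=large_pos,
        large_peak_mean=float(np.mean(sig[large_idx])),
        small_peak_positions=pos[small_idx],
        small_peak_mean=float(np.mean(sig[small_idx])) if len(small_idx) else float("nan"),
        head_domain_size=float(np.mean(head_gaps)) if head_gaps else float("nan"),
        tail_domain_size=float(np.mean(tail_gaps)) if tail_gaps else float("nan"),
    )


def _split_large_small(heights: np.ndarray) -> np.ndarray:
    """Boolean mask of the "large" cluster: 2-means on peak heights,
    threshold at the midpoint of the two cluster means."""
    if len(heights) < 2 or np.allclose(heights, heights[0]):
        return np.ones(len(heights), dtype=bool)
    lo, hi = heights.min(), heights.max()
    thr = 0.5 * (lo + hi)
    for _ in range(50):
        hi_mean = heights[heights >= thr].mean()
        lo_mean = heights[heights < thr].mean() if (heights < thr).any() else lo
        new = 0.5 * (hi_mean + lo_mean)
        if abs(new - thr) < 1e-12:
            break
        thr = new
    return heights >= thr
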