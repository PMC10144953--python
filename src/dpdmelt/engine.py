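"""DPD equations of motion in the NVT ensemble.

The pair interaction is the standard soft DPD triple: a conservative
repulsion a_ij (1 - r/rc) r_hat, a pairwise drag -gamma w^2 (v_ij . r_hat)
r_hat and a matched random kick sigma w zeta dt^{-1/2} r_hat, with
sigma^2 = 2 gamma kBT so that the pair forces act as a momentum-conserving
thermostat.  Chains add harmonic springs and a bending potential on the
rigid head group.  Time integration uses the modified velocity-Verlet
scheme with an adjustable lambda (default 0.65, the empirical choice for
sigma = 3): positions advance with the current force, a predicted velocity
v + lambda dt f enters the new force evaluation, and the velocity is
corrected with the mean of old and new forces.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .forcefield import ConfigurationError, ForceFieldParams
from .state import EnergyTrace, Frame, Trajectory
from .topology import Topology

log = logging.getLogger(__name__)

_NOISE_CODE = {"gaussian": K.NOISE_GAUSSIAN, "uniform": K.NOISE_UNIFORM}
_SLAB_CODE = {None: K.SLAB_OFF, "ik": K.SLAB_IK, "midpoint": K.SLAB_MIDPOINT}


@dataclass
class RunConfig:
    """Integration parameters.

    dt is the time step in tau (0.01 is the standard soft-potential
    choice); lambda_vv the velocity-prediction factor of the modified
    velocity-Verlet scheme; sample_every / thermo_every are the trajectory
    and energy-trace strides in steps.
    """

    dt: float = 0.01
    n_steps: int = 1000
    lambda_vv: float = 0.65
    seed: int = 0
    sample_every: int = 100
    thermo_every: int = 100

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if not 0 < self.lambda_vv <= 1:
            raise ConfigurationError("lambda_vv must lie in (0, 1]")
        if self.n_steps < 0:
            raise ConfigurationError("n_steps must be non-negative")
        if self.sample_every < 1 or self.thermo_every < 1:
            raise ConfigurationError("strides must be >= 1")


# ---------------------------------------------------------------------------
# scalar force laws (the per-pair physics, usable standalone)
# ---------------------------------------------------------------------------

def conservative_force(r_vec: np.ndarray, a: float, rc: float = 1.0) -> np.ndarray:
    """Soft repulsion a (1 - r/rc) r_hat for r < rc, zero beyond the cutoff.

    ``r_vec`` is the minimum-image separation r_i - r_j; the returned force
    acts on bead i.  The potential is finite at r = 0 (soft core), but the
    direction is then undefined: a zero vector is returned with a warning.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec)
    if r >= rc:
        return np.zeros(3)
    if r < 1e-12:
        warnings.warn("coincident beads: conservative force direction undefined")
        return np.zeros(3)
    return a * (1.0 - r / rc) * r_vec / r


def dissipative_random_force(
    r_vec: np.ndarray,
    v_rel: np.ndarray,
    gamma: float,
    sigma: float,
    dt: float,
    rng: np.random.Generator,
    rc: float = 1.0,
    kT: float = 1.0,
) -> np.ndarray:
    """Thermostat pair force F_D + F_R projected along r_hat.

    F_D = -gamma w(r)^2 (v_rel . r_hat) r_hat and
    F_R = sigma w(r) zeta dt^{-1/2} r_hat with zeta ~ N(0, 1) drawn from
    ``rng``.  Requires the fluctuation-dissipation match
    sigma^2 = 2 gamma kT.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if not np.isclose(sigma**2, 2.0 * gamma * kT, rtol=1e-10):
        raise ConfigurationError("sigma^2 must equal 2*gamma*kT")
    r_vec = np.asarray(r_vec, dtype=float)
    v_rel = np.asarray(v_rel, dtype=float)
    r = np.linalg.norm(r_vec)
    if r >= rc or r < 1e-12:
        return np.zeros(3)
    e = r_vec / r
    w = 1.0 - r / rc
    zeta = rng.normal()
    fmag = -gamma * w * w * float(v_rel @ e) + sigma * w * zeta / np.sqrt(dt)
    return fmag * e


def bond_force(r_vec: np.ndarray, ks: float, rs: float) -> np.ndarray:
    """Harmonic spring ks (1 - r/rs) r_hat on bead i of a bonded pair."""
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec)
    if r < 1e-12:
        raise ValueError("bonded beads coincide: bond force undefined")
    return ks * (1.0 - r / rs) * r_vec / r


def angle_force(
    r_i: np.ndarray, r_j: np.ndarray, r_k: np.ndarray, k_theta: float, theta0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forces on (i, j, k) from U = k_theta (theta - theta0)^2, j central.

    Total force and torque vanish.  At theta = theta0 = pi (straight
    triple) the force is zero: the 1/sin(theta) factor cancels against
    (theta - theta0).
    """
    pos = np.vstack([r_i, r_j, r_k]).astype(float)
    forces = np.zeros((3, 3))
    virial = np.zeros((3, 3))
    slab = np.zeros((0, 3))
    angles = np.array([[0, 1, 2]], dtype=np.int64)
    big = 1e12  # effectively non-periodic
    _, ndeg = K.angle_forces(
        pos, angles, k_theta, theta0, big, forces, virial, slab, 0, 1.0, K.SLAB_OFF
    )
    if ndeg:
        raise ValueError("zero-length bond vector in angle triple")
    return forces[0], forces[1], forces[2]


def angle_energy(
    r_i: np.ndarray, r_j: np.ndarray, r_k: np.ndarray, k_theta: float, theta0: float
) -> float:
    u = np.asarray(r_i, float) - np.asarray(r_j, float)
    w = np.asarray(r_k, float) - np.asarray(r_j, float)
    c = float(u @ w / (np.linalg.norm(u) * np.linalg.norm(w)))
    theta = np.arccos(np.clip(c, -1.0, 1.0))
    return k_theta * (theta - theta0) ** 2


# ---------------------------------------------------------------------------
# full-system force evaluation
# ---------------------------------------------------------------------------

def compute_forces(
    frame: Frame,
    topology: Topology,
    ff: ForceFieldParams,
    dt: float = 0.01,
    seed: int = 0,
    step_index: int = 0,
    include_dissipative: bool = True,
    include_random: bool = True,
    include_conservative: bool = True,
    neighbor: str = "auto",
    slab_profile: str | None = None,
    n_slabs: int = 0,
):
    """Evaluate all forces on a frame.

    Returns ``(forces, epot, virial)`` and, when ``slab_profile`` is "ik"
    or "midpoint", additionally the (n_slabs, 3) per-slab diagonal virial.
    ``virial`` is the full 3x3 tensor  W_ab = sum_pairs F_ij,a d_ij,b
    (pair + bond + decomposed angle terms).
    """
    L = frame.box_length
    rc = ff.cutoff
    n = frame.n_beads
    forces = np.zeros((n, 3))
    virial = np.zeros((3, 3))
    slab_mode = _SLAB_CODE[slab_profile]
    if slab_mode != K.SLAB_OFF:
        if n_slabs < 1:
            raise ValueError("n_slabs must be >= 1 for a slab profile")
        slab_virial = np.zeros((n_slabs, 3))
        slab_w = L / n_slabs
    else:
        slab_virial = np.zeros((0, 3))
        slab_w = 1.0
        n_slabs = 0

    if neighbor == "auto":
        neighbor = "cell" if L / rc >= 3.0 and n > 64 else "all"
    if neighbor not in ("cell", "all"):
        raise ValueError(f"unknown neighbor search {neighbor!r}")
    types = np.ascontiguousarray(topology.bead_types, dtype=np.int64)
    epot, ndeg = K.pair_forces(
        frame.positions, frame.velocities, types, L,
        ff.interaction_matrix, ff.gamma, ff.sigma, rc, 1.0 / np.sqrt(dt),
        seed, step_index, _NOISE_CODE[ff.noise],
        include_conservative, include_dissipative, include_random,
        forces, virial, slab_virial, n_slabs, slab_w, slab_mode,
        neighbor=neighbor,
    )
    if ndeg:
        log.warning("%d coincident pair(s): zero pair force assigned", ndeg)
    if len(topology.bonds):
        e_b, ndeg_b = K.bond_forces(
            frame.positions, topology.bonds, ff.bond_k, ff.bond_r0, L,
            forces, virial, slab_virial, n_slabs, slab_w, slab_mode,
        )
        if ndeg_b:
            raise ValueError(f"{ndeg_b} bond(s) of zero length: bonded beads coincide")
        epot += e_b
    if len(topology.angles):
        e_a, _ = K.angle_forces(
            frame.positions, topology.angles, ff.angle_k, ff.angle_theta0, L,
            forces, virial, slab_virial, n_slabs, slab_w, slab_mode,
        )
        epot += e_a
    if slab_mode != K.SLAB_OFF:
        return forces, epot, virial, slab_virial
    return forces, epot, virial


def kinetic_energy(frame: Frame, mass: float = 1.0) -> float:
    return 0.5 * mass * float(np.sum(frame.velocities**2))


def kinetic_temperature(frame: Frame, mass: float = 1.0) -> float:
    """Instantaneous kinetic temperature from the equipartition theorem,
    with the three centre-of-mass degrees of freedom removed."""
    n = frame.n_beads
    return 2.0 * kinetic_energy(frame, mass) / (3.0 * n - 3.0)


def step(
    frame: Frame,
    topology: Topology,
    ff: ForceFieldParams,
    cfg: RunConfig,
    step_index: int,
    neighbor: str = "auto",
):
    """Advance one modified velocity-Verlet step in place.

    ``frame.forces`` must hold the forces for the current positions (the
    caller primes them once; ``run`` maintains the invariant).  Returns the
    potential energy and virial of the *new* force evaluation.
    """
    dt = cfg.dt
    m = ff.mass
    f_old = frame.forces.copy()
    frame.positions += dt * frame.velocities + 0.5 * dt * dt * (f_old / m)
    frame.wrap()
    v_old = frame.velocities.copy()
    frame.velocities[:] = v_old + cfg.lambda_vv * dt * (f_old / m)  # prediction
    f_new, epot, virial = compute_forces(
        frame, topology, ff, dt=dt, seed=cfg.seed, step_index=step_index + 1,
        neighbor=neighbor,
    )
    if not np.isfinite(f_new).all():
        raise FloatingPointError(
            f"non-finite force at step {step_index}: integration failed "
            "(check time step and initial overlaps)"
        )
    frame.velocities[:] = v_old + 0.5 * dt * (f_old + f_new) / m
    frame.forces[:] = f_new
    frame.time += dt
    return epot, virial


def run(
    frame: Frame,
    topology: Topology,
    ff: ForceFieldParams,
    cfg: RunConfig,
    neighbor: str = "auto",
) -> tuple[Trajectory, EnergyTrace]:
    """Integrate ``cfg.n_steps`` steps, sampling frames every
    ``sample_every`` steps and energies every ``thermo_every`` steps.

    The trajectory stores frame copies and the instantaneous pressure
    tensor (kinetic part, virial part) of each sampled frame.  The initial
    frame is always included.  Reproducible per ``cfg.seed``.
    """
    frame = frame.copy()
    V = frame.box_length**3
    f0, epot, virial = compute_forces(
        frame, topology, ff, dt=cfg.dt, seed=cfg.seed, step_index=0, neighbor=neighbor
    )
    frame.forces[:] = f0

    traj = Trajectory()
    steps_rec, pot_rec, kin_rec = [], [], []

    def record(idx, epot_now, virial_now):
        if idx % cfg.sample_every == 0 or idx == cfg.n_steps:
            kin = _kinetic_tensor(frame, ff.mass)
            traj.append(frame.copy(), np.stack([kin / V, virial_now / V]))
        if idx % cfg.thermo_every == 0 or idx == cfg.n_steps:
            steps_rec.append(idx)
            pot_rec.append(epot_now)
            kin_rec.append(kinetic_energy(frame, ff.mass))

    record(0, epot, virial)
    for i in range(cfg.n_steps):
        epot, virial = step(frame, topology, ff, cfg, i, neighbor=neighbor)
        record(i + 1, epot, virial)
    trace = EnergyTrace(np.array(steps_rec), np.array(pot_rec), np.array(kin_rec))
    return traj, trace


def _kinetic_tensor(frame: Frame, mass: float) -> np.ndarray:
    v = frame.velocities
    return mass * (v.T @ v)
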