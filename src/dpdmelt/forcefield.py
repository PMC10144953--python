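"""DPD force-field parameters.

All quantities are in reduced DPD units: lengths in the pair cutoff rc,
energies in kBT, masses in the bead mass m, time in tau = sqrt(m rc^2 / kBT).
The bead types are H (hydrophilic head), T (hydrophobic tail) and N
(nanoparticle), encoded as integers 0, 1, 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: integer codes for the three bead species
TYPE_H, TYPE_T, TYPE_N = 0, 1, 2
TYPE_NAMES = ("H", "T", "N")
N_TYPES = 3


class ConfigurationError(ValueError):
    """Raised when force-field or run parameters are inconsistent."""


@dataclass
class ForceFieldParams:
    """Complete DPD interaction parameter set.

    Parameters
    ----------
    interaction_matrix : (3, 3) array
        Maximum conservative repulsion ``a_ij`` between bead types, in
        kBT/rc.  Must be symmetric and non-negative.  The default is the
        like/unlike convention ``a_ii = 25``, ``a_ij = 100``.
    gamma : float
        Pairwise friction coefficient of the dissipative force.
    sigma : float
        Noise amplitude of the random force.  The fluctuation-dissipation
        relation ``sigma**2 == 2 * gamma * kT`` is enforced at construction.
    cutoff : float
        Pair cutoff rc; the length unit (1 by definition).
    bond_k, bond_r0 : float
        Harmonic spring constant ks and equilibrium bond length rs of the
        intra-chain bonds.
    angle_k, angle_theta0 : float
        Bending constant k_theta and equilibrium angle theta0 (radians) of
        the three-bead angle potential applied to head triples.
    kT, mass : float
        Thermal energy and bead mass; both 1 in reduced units.
    noise : {"gaussian", "uniform"}
        Distribution of the pair noise zeta_ij: standard normal, or uniform
        rescaled to unit variance.  Both are valid DPD noises.
    """

    interaction_matrix: np.ndarray = field(
        default_factory=lambda: np.array(
            [[25.0, 100.0, 100.0], [100.0, 25.0, 100.0], [100.0, 100.0, 25.0]]
        )
    )
    gamma: float = 4.5
    sigma: float = 3.0
    cutoff: float = 1.0
    bond_k: float = 120.0
    bond_r0: float = 0.7
    angle_k: float = 6.0
    angle_theta0: float = np.pi
    kT: float = 1.0
    mass: float = 1.0
    noise: str = "gaussian"

    def __post_init__(self) -> None:
        a = np.asarray(self.interaction_matrix, dtype=float)
        if a.shape != (N_TYPES, N_TYPES):
            raise ConfigurationError(
                f"interaction matrix must be {N_TYPES}x{N_TYPES}, got {a.shape}"
            )
        if not np.allclose(a, a.T):
            raise ConfigurationError("interaction matrix must be symmetric")
        if (a < 0).any():
            raise ConfigurationError("repulsion parameters must be non-negative")
        self.interaction_matrix = a
        if self.cutoff <= 0:
            raise ConfigurationError("cutoff must be positive")
        if not self.bond_r0 < self.cutoff:
            raise ConfigurationError("equilibrium bond length must be below the cutoff")
        if not np.isclose(self.sigma**2, 2.0 * self.gamma * self.kT, rtol=1e-10):
            raise ConfigurationError(
                "fluctuation-dissipation violated: require sigma^2 == 2*gamma*kT "
                f"(got sigma^2={self.sigma**2:.6g}, 2*gamma*kT={2*self.gamma*self.kT:.6g})"
            )
        if self.noise not in ("gaussian", "uniform"):
            raise ConfigurationError(f"unknown noise distribution {self.noise!r}")

    def a(self, type_i: int, type_j: int) -> float:
        """Repulsion parameter between two bead types."""
        return float(self.interaction_matrix[type_i, type_j])

    @classmethod
    def default(cls) -> "ForceFieldParams":
        """The standard lipid-nanoparticle melt parameter set."""
        return cls()


def flory_huggins_chi(a_unlike: float, a_like: float = 25.0) -> float:
    """Effective Flory-Huggins parameter chi = 0.286 (a_ij - a_ii)."""
    return 0.286 * (a_unlike - a_like)
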