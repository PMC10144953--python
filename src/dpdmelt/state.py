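"""Simulation state containers: a single frame and a sampled trajectory."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Frame:
    """One snapshot: positions wrapped into [0, D), velocities, forces,
    simulation time (tau) and box side D (rc)."""

    positions: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray
    box_length: float
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.forces = np.ascontiguousarray(self.forces, dtype=np.float64)
        n = len(self.positions)
        if self.velocities.shape != (n, 3) or self.forces.shape != (n, 3):
            raise ValueError("positions, velocities and forces must share shape (n, 3)")
        if self.box_length <= 0:
            raise ValueError("box length must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def wrap(self) -> None:
        """Wrap positions into [0, D) in place."""
        np.mod(self.positions, self.box_length, out=self.positions)

    def copy(self) -> "Frame":
        return Frame(
            self.positions.copy(),
            self.velocities.copy(),
            self.forces.copy(),
            self.box_length,
            self.time,
        )

    @classmethod
    def zeros(cls, n: int, box_length: float) -> "Frame":
        return cls(
            np.zeros((n, 3)), np.zeros((n, 3)), np.zeros((n, 3)), box_length, 0.0
        )


@dataclass
class Trajectory:
    """Frames sampled at a fixed stride, with per-sample pressure tensors
    recorded by the engine when available (kinetic + virial, 3x3 each)."""

    frames: list = field(default_factory=list)
    pressure_tensors: list = field(default_factory=list)

    def append(self, frame: Frame, pressure: np.ndarray | None = None) -> None:
        self.frames.append(frame)
        if pressure is not None:
            self.pressure_tensors.append(np.asarray(pressure))

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


@dataclass
class EnergyTrace:
    """Total, potential and kinetic energy per diagnostics sample, in kBT."""

    steps: np.ndarray
    potential: np.ndarray
    kinetic: np.ndarray

    @property
    def total_energy(self) -> np.ndarray:
        return self.potential + self.kinetic

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps)
        self.potential = np.asarray(self.potential, dtype=float)
        self.kinetic = np.asarray(self.kinetic, dtype=float)
        if not (len(self.steps) == len(self.potential) == len(self.kinetic)):
            raise ValueError("energy trace columns must have equal length")
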