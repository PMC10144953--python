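"""File formats and experiment configuration.

Structures go out as LAMMPS data files (atom-style ``angle``: bonds +
angles) and extended XYZ; trajectories as LAMMPS dump text (id type x y z
vx vy vz); profiles and series as tidy CSV with a units line in the
header; configs are YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .forcefield import ForceFieldParams, TYPE_NAMES
from .state import Frame, Trajectory
from .topology import Topology


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "n_head", "n_tail", "phi_np_list", "box_length", "density", "phase",
    "dt", "n_steps", "lambda_vv", "seeds", "sample_every", "thermo_every",
    "bin_width", "slab_width", "plateau_fraction", "output_dir",
    "a_like", "a_unlike", "noise", "angle_scheme",
}


@dataclass
class ExperimentConfig:
    """Validated parameters of one lamellar/hexagonal study.

    Defaults are the standard protocol: D = 30 rc, rho = 3, dt = 0.01 tau,
    sigma = 3 / gamma = 4.5 (via the force field), lambda = 0.65,
    concentrations 0, 0.03, 0.05, 0.15.
    """

    n_head: int = 3
    n_tail: int = 10
    phi_np_list: list = field(default_factory=lambda: [0.0, 0.03, 0.05, 0.15])
    box_length: float = 30.0
    density: float = 3.0
    phase: str = "lamellar"
    dt: float = 0.01
    n_steps: int = 300_000
    lambda_vv: float = 0.65
    seeds: list = field(default_factory=lambda: [1, 2, 3, 4, 5, 6])
    sample_every: int = 1000
    thermo_every: int = 500
    bin_width: float = 0.25
    slab_width: float = 0.25
    plateau_fraction: float = 1.0 / 3.0
    output_dir: str = "dpdmelt_out"
    a_like: float = 25.0
    a_unlike: float = 100.0
    noise: str = "gaussian"
    angle_scheme: str = "head"

    def __post_init__(self) -> None:
        if self.n_head < 1 or self.n_tail < 1:
            raise ValueError("n_head and n_tail must be >= 1")
        if any(p < 0 for p in self.phi_np_list):
            raise ValueError("nanoparticle concentrations must be non-negative")
        if self.box_length <= 0 or self.density <= 0:
            raise ValueError("box_length and density must be positive")
        if self.phase not in ("lamellar", "hexagonal", "random"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 < self.lambda_vv <= 1:
            raise ValueError("lambda_vv must lie in (0, 1]")
        if not self.seeds:
            raise ValueError("seeds list must be non-empty")
        if not 0 < self.plateau_fraction <= 1:
            raise ValueError("plateau_fraction must lie in (0, 1]")

    def forcefield(self) -> ForceFieldParams:
        a = np.full((3, 3), self.a_unlike)
        np.fill_diagonal(a, self.a_like)
        return ForceFieldParams(interaction_matrix=a, noise=self.noise)


def read_config(path) -> ExperimentConfig:
    """Read and validate a YAML experiment config; unknown keys fail."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(path, 1, "config must be a YAML mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ExperimentConfig(**raw)


def write_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# LAMMPS data / dump, extended XYZ
# ---------------------------------------------------------------------------

def write_lammps_data(topology: Topology, frame: Frame, path) -> None:
    """LAMMPS data file, atom-style ``angle`` (id mol type x y z)."""
    D = frame.box_length
    n = topology.n_beads
    with open(path, "w") as fh:
        fh.write("lipid-nanoparticle melt (reduced DPD units)\n\n")
        fh.write(f"{n} atoms\n{len(topology.bonds)} bonds\n{len(topology.angles)} angles\n\n")
        fh.write("3 atom types\n1 bond types\n1 angle types\n\n")
        for ax in "xyz":
            fh.write(f"0.0 {D:.10g} {ax}lo {ax}hi\n")
        fh.write("\nMasses\n\n1 1.0\n2 1.0\n3 1.0\n\nAtoms\n\n")
        for i in range(n):
            mol = topology.chain_id[i] + 1 if topology.chain_id[i] >= 0 else 0
            t = topology.bead_types[i] + 1
            x, y, z = frame.positions[i]
            fh.write(f"{i + 1} {mol} {t} {x:.10g} {y:.10g} {z:.10g}\n")
        if len(topology.bonds):
            fh.write("\nBonds\n\n")
            for b, (i, j) in enumerate(topology.bonds):
                fh.write(f"{b + 1} 1 {i + 1} {j + 1}\n")
        if len(topology.angles):
            fh.write("\nAngles\n\n")
            for a, (i, j, k) in enumerate(topology.angles):
                fh.write(f"{a + 1} 1 {i + 1} {j + 1} {k + 1}\n")


def read_lammps_data(path):
    """Read back a data file written by :func:`write_lammps_data`.

    Returns ``(topology_arrays, frame)`` where topology_arrays is a dict
    with bead types (0-based), molecule ids, bonds and angles.
    """
    counts = {"atoms": 0, "bonds": 0, "angles": 0}
    box = {}
    atoms, bonds, angles = [], [], []
    section = None
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, 1):
        s = line.split("#")[0].strip()
        if not s:
            continue
        parts = s.split()
        if lineno == 1 and section is None and not parts[0].lstrip("-").isdigit():
            continue  # title line
        if len(parts) >= 2 and parts[1] in counts:
            counts[parts[1]] = int(parts[0])
            continue
        if len(parts) == 4 and parts[2].endswith("lo"):
            box[parts[2][0]] = (float(parts[0]), float(parts[1]))
            continue
        if parts[0] in ("Masses", "Atoms", "Bonds", "Angles", "Velocities"):
            section = parts[0]
            continue
        if len(parts) == 3 and parts[1] == "atom" and parts[2] == "types":
            continue
        if len(parts) == 3 and parts[2] == "types":
            continue
        try:
            if section == "Atoms":
                atoms.append([float(p) for p in parts[:6]])
            elif section == "Bonds":
                bonds.append([int(parts[2]) - 1, int(parts[3]) - 1])
            elif section == "Angles":
                angles.append([int(parts[2]) - 1, int(parts[3]) - 1, int(parts[4]) - 1])
        except (ValueError, IndexError) as exc:
            raise ParseError(path, lineno, f"malformed {section} record: {exc}")
    if len(atoms) != counts["atoms"]:
        raise ParseError(path, len(lines), "atom count mismatch with header")
    atoms.sort(key=lambda r: r[0])
    arr = np.asarray(atoms)
    D = box["x"][1] - box["x"][0]
    frame = Frame.zeros(len(atoms), D)
    frame.positions[:] = arr[:, 3:6]
    topo = {
        "bead_types": arr[:, 2].astype(int) - 1,
        "mol": arr[:, 1].astype(int),
        "bonds": np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        "angles": np.asarray(angles, dtype=np.int64).reshape(-1, 3),
    }
    return topo, frame


def write_xyz(topology: Topology, frame: Frame, path, comment: str = "") -> None:
    """Extended XYZ with a Lattice record and species column."""
    D = frame.box_length
    with open(path, "w") as fh:
        fh.write(f"{topology.n_beads}\n")
        fh.write(
            f'Lattice="{D} 0 0 0 {D} 0 0 0 {D}" Properties=species:S:1:pos:R:3 {comment}\n'
        )
        for t, (x, y, z) in zip(topology.bead_types, frame.positions):
            fh.write(f"{TYPE_NAMES[t]} {x:.10g} {y:.10g} {z:.10g}\n")


def write_lammps_dump(trajectory, path, topology: Topology | None = None) -> None:
    """Text LAMMPS dump: id type x y z vx vy vz per frame."""
    frames = trajectory.frames if isinstance(trajectory, Trajectory) else list(trajectory)
    with open(path, "w") as fh:
        for k, frame in enumerate(frames):
            D = frame.box_length
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{int(round(frame.time * 1e6))}\n")  # integer step label
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{frame.n_beads}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for _ in range(3):
                fh.write(f"0.0 {D:.10g}\n")
            fh.write("ITEM: ATOMS id type x y z vx vy vz\n")
            types = (
                topology.bead_types + 1
                if topology is not None
                else np.ones(frame.n_beads, dtype=int)
            )
            for i in range(frame.n_beads):
                x, y, z = frame.positions[i]
                vx, vy, vz = frame.velocities[i]
                fh.write(
                    f"{i + 1} {types[i]} {x:.8g} {y:.8g} {z:.8g} {vx:.8g} {vy:.8g} {vz:.8g}\n"
                )


def read_lammps_dump(path):
    """Read a text LAMMPS dump.  Returns ``(trajectory, has_velocities)``;
    velocity-requiring analyses must refuse when the flag is False."""
    traj = Trajectory()
    has_velocities = True
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("ITEM: TIMESTEP"):
            raise ParseError(path, i + 1, f"expected ITEM: TIMESTEP, got {line!r}")
        step = int(lines[i + 1])
        if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise ParseError(path, i + 3, "expected ITEM: NUMBER OF ATOMS")
        n = int(lines[i + 3])
        if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
            raise ParseError(path, i + 5, "expected ITEM: BOX BOUNDS")
        lo, hi = (float(v) for v in lines[i + 5].split()[:2])
        D = hi - lo
        header = lines[i + 8].strip()
        if not header.startswith("ITEM: ATOMS"):
            raise ParseError(path, i + 9, "expected ITEM: ATOMS")
        cols = header.split()[2:]
        frame_has_v = all(c in cols for c in ("vx", "vy", "vz"))
        has_velocities = has_velocities and frame_has_v
        ix = {c: cols.index(c) for c in cols}
        frame = Frame.zeros(n, D)
        for a in range(n):
            parts = lines[i + 9 + a].split()
            if len(parts) != len(cols):
                raise ParseError(path, i + 10 + a, "wrong number of columns")
            bead = int(parts[ix["id"]]) - 1
            frame.positions[bead] = [
                float(parts[ix["x"]]), float(parts[ix["y"]]), float(parts[ix["z"]])
            ]
            if frame_has_v:
                frame.velocities[bead] = [
                    float(parts[ix["vx"]]), float(parts[ix["vy"]]), float(parts[ix["vz"]])
                ]
        frame.time = step / 1e6
        traj.append(frame)
        i += 9 + n
    return traj, has_velocities


# ---------------------------------------------------------------------------
# tidy CSV with units metadata
# ---------------------------------------------------------------------------

def write_profile_csv(profile, path, value_units: str = "beads/rc^3") -> None:
    """Axial/radial profile as tidy CSV (bin, type, value) with a units
    header comment."""
    rows = []
    centers = profile.bin_centers
    for name, dens in profile.density_per_type.items():
        for c, v in zip(centers, dens):
            rows.append((c, name, v))
    df = pd.DataFrame(rows, columns=["bin_center", "type", "density"])
    with open(path, "w") as fh:
        fh.write(f"# units: bin_center [rc], density [{value_units}]\n")
        df.to_csv(fh, index=False)


def write_series_csv(columns: dict, path, units: dict) -> None:
    """Generic time-series CSV; ``units`` maps column -> unit string."""
    df = pd.DataFrame(columns)
    with open(path, "w") as fh:
        unit_str = ", ".join(f"{k} [{v}]" for k, v in units.items())
        fh.write(f"# units: {unit_str}\n")
        df.to_csv(fh, index=False)


def read_series_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
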