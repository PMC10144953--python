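"""End-to-end study orchestration: build -> simulate -> analyze, per
nanoparticle concentration and per seed, pooled across seeds.

The artifact tree under ``config.output_dir`` is a pure function of
(config, seeds, code version):

    phi_<phi>/seed_<s>/energy.csv         step, E_pot, E_kin, E_tot (kBT)
    phi_<phi>/seed_<s>/density.csv        final-frame axial densities
    phi_<phi>/seed_<s>/order.csv          order-parameter profile
    phi_<phi>/seed_<s>/gyration.csv       Rg component series
    phi_<phi>/seed_<s>/np_layering_*.csv  nanoparticle profiles over time
    phi_<phi>/seed_<s>/tension_profile.csv, tension_series.csv
    phi_<phi>/seed_<s>/final.data, final.xyz
    summary.json                          pooled means +/- sd per observable
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .builder import init_velocities, place_preassembled, place_random_melt
from .engine import RunConfig, run
from .io import ExperimentConfig, write_lammps_data, write_profile_csv, write_series_csv, write_xyz
from .mechanics import tension_profile, tension_series
from .observables import axial_density, gyration_components, nanoparticle_layering, order_parameter
from .topology import BoxSpec, build_lipid_topology, lipid_count, nanoparticle_count

log = logging.getLogger(__name__)


def build_system(config: ExperimentConfig, phi_np: float, seed: int):
    """Topology + initial frame for one concentration and seed."""
    box = BoxSpec(config.box_length, config.density)
    n_np = nanoparticle_count(phi_np, config.box_length)
    m = config.n_head + config.n_tail
    n_lip = lipid_count(config.density, config.box_length, m, n_np)
    topo = build_lipid_topology(
        config.n_head, config.n_tail, n_lip, n_np, angle_scheme=config.angle_scheme
    )
    if config.phase == "random":
        frame = place_random_melt(topo, box, seed)
    else:
        frame = place_preassembled(topo, box, config.phase, seed)
    ff = config.forcefield()
    frame = init_velocities(frame, ff.kT, seed + 7919)
    return topo, frame, ff


def _analyze(config, topo, ff, traj, trace, outdir: Path, phi_np: float):
    outdir.mkdir(parents=True, exist_ok=True)
    write_series_csv(
        {
            "step": trace.steps,
            "E_pot": trace.potential,
            "E_kin": trace.kinetic,
            "E_tot": trace.total_energy,
        },
        outdir / "energy.csv",
        {"step": "1", "E_pot": "kBT", "E_kin": "kBT", "E_tot": "kBT"},
    )
    final = traj.frames[-1]
    density = axial_density(final, topo, config.bin_width)
    write_profile_csv(density, outdir / "density.csv")

    # observables averaged over the plateau window (final third of samples)
    n_plateau = max(1, int(round(len(traj) * config.plateau_fraction)))
    plateau_frames = traj.frames[-n_plateau:]

    order = order_parameter(plateau_frames, topo, config.bin_width)
    write_series_csv(
        {"z": order.bin_centers, "p2": order.p2, "n_chains": order.n_chains},
        outdir / "order.csv",
        {"z": "rc", "p2": "1", "n_chains": "1"},
    )
    gyr = gyration_components(traj, topo)
    write_series_csv(
        {"time": gyr.times, "rg_xx": gyr.rg_xx, "rg_yy": gyr.rg_yy, "rg_zz": gyr.rg_zz},
        outdir / "gyration.csv",
        {"time": "tau", "rg_xx": "rc", "rg_yy": "rc", "rg_zz": "rc"},
    )
    if topo.n_nanoparticles:
        for t, prof in nanoparticle_layering(traj, topo, config.bin_width):
            write_profile_csv(prof, outdir / f"np_layering_t{t:.0f}.csv")
    else:
        (outdir / "np_layering_absent.txt").write_text(
            "no nanoparticles at phi_np=0: layering profiles not produced\n"
        )
    series = tension_series(traj, topo, ff)
    write_series_csv(
        {"time": series.times, "sigma_z": series.sigma_z, "running_mean": series.running_mean},
        outdir / "tension_series.csv",
        {"time": "tau", "sigma_z": "kBT/rc^3", "running_mean": "kBT/rc^3"},
    )
    profile = tension_profile(plateau_frames, topo, ff, config.slab_width)
    write_series_csv(
        {"z": profile.slab_centers, "sigma_z": profile.sigma_z},
        outdir / "tension_profile.csv",
        {"z": "rc", "sigma_z": "kBT/rc^3"},
    )

    n_g = max(1, int(round(len(gyr.times) * config.plateau_fraction)))
    return {
        "tension_plateau": series.plateau_mean(config.plateau_fraction),
        "rg_xx": float(np.mean(gyr.rg_xx[-n_g:])),
        "rg_yy": float(np.mean(gyr.rg_yy[-n_g:])),
        "rg_zz": float(np.mean(gyr.rg_zz[-n_g:])),
        "energy_final": float(trace.total_energy[-1]),
        "n_samples": len(traj),
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full study: every concentration x every seed; pooled
    mean +/- sd per observable.  Per-replicate failures are isolated and
    recorded as missing cells."""
    root = Path(config.output_dir)
    root.mkdir(parents=True, exist_ok=True)
    summary = {"config": config.__dict__.copy(), "version": __version__, "cells": {}}
    for phi in config.phi_np_list:
        per_seed = {}
        for seed in config.seeds:
            cell = f"phi={phi:g}, seed={seed}"
            outdir = root / f"phi_{phi:g}" / f"seed_{seed}"
            try:
                topo, frame, ff = build_system(config, phi, seed)
                cfg = RunConfig(
                    dt=config.dt,
                    n_steps=config.n_steps,
                    lambda_vv=config.lambda_vv,
                    seed=seed,
                    sample_every=config.sample_every,
                    thermo_every=config.thermo_every,
                )
                traj, trace = run(frame, topo, ff, cfg)
                stats = _analyze(config, topo, ff, traj, trace, outdir, phi)
                outdir.mkdir(parents=True, exist_ok=True)
                write_lammps_data(topo, traj.frames[-1], outdir / "final.data")
                write_xyz(topo, traj.frames[-1], outdir / "final.xyz")
                per_seed[str(seed)] = stats
                log.info("%s done: %s", cell, stats)
            except Exception as exc:  # noqa: BLE001 - isolate replicate failures
                log.error("%s FAILED: %s", cell, exc)
                per_seed[str(seed)] = {"error": str(exc)}
        pooled = _pool(per_seed)
        summary["cells"][f"{phi:g}"] = {"per_seed": per_seed, "pooled": pooled}
    with open(root / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def _pool(per_seed: dict) -> dict:
    ok = [v for v in per_seed.values() if "error" not in v]
    if not ok:
        return {"n_seeds": 0}
    keys = [k for k in ok[0] if k != "n_samples"]
    pooled = {"n_seeds": len(ok), "n": sum(v["n_samples"] for v in ok)}
    for k in keys:
        vals = np.array([v[k] for v in ok], dtype=float)
        pooled[k] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    return pooled
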