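"""Trajectory store: plain-text, greppable, lossless.

A trajectory directory contains

* ``frames.xyz`` — extended-XYZ monomer frames; the atom name ``f{i}m{j}``
  encodes filament and monomer index, coordinates at full (17 significant
  digit) precision so round trips are bit-identical;
* ``motors.tsv`` — motor roster per frame (frame, fil_a, mon_a, fil_b, mon_b);
* ``wall.tsv`` — wall node coordinates per frame (frame, node, x, y), empty
  in fixed-volume runs;
* ``observables.tsv`` — per-frame observable table;
* ``summary.json`` — parameters, seed, final state and fit results.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, analysis
from .dynamics import Frame, Schedule, Trajectory
from .params import ModelParams

__all__ = ["write_trajectory", "read_trajectory", "build_run_summary", "TrajectoryCorruptionError"]

FMT = "%.17g"


class TrajectoryCorruptionError(RuntimeError):
    def __init__(self, msg: str, last_good_frame: int):
        super().__init__(f"{msg} (last good frame: {last_good_frame})")
        self.last_good_frame = last_good_frame


def write_trajectory(traj: Trajectory, outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "frames.xyz", "w") as fx:
        for k, fr in enumerate(traj.frames):
            N, M, _ = fr.positions.shape
            fx.write(f"{N * M}\n")
            fx.write(f'Frame={k} Time={FMT % fr.time} N={N} M={M} '
                     f'Properties=species:S:1:pos:R:3\n')
            flat = fr.positions.reshape(N * M, 3)
            for idx in range(N * M):
                x, y, z = flat[idx]
                fx.write(f"f{idx // M}m{idx % M} {FMT % x} {FMT % y} {FMT % z}\n")
    with open(out / "motors.tsv", "w") as fm:
        fm.write("frame\tfil_a\tmon_a\tfil_b\tmon_b\n")
        for k, fr in enumerate(traj.frames):
            for fa, ma, fb, mb in fr.motors:
                fm.write(f"{k}\t{fa}\t{ma}\t{fb}\t{mb}\n")
    with open(out / "wall.tsv", "w") as fw:
        fw.write("frame\tnode\tx\ty\n")
        for k, fr in enumerate(traj.frames):
            if fr.wall_nodes is not None:
                for ni, (x, y) in enumerate(fr.wall_nodes):
                    fw.write(f"{k}\t{ni}\t{FMT % x}\t{FMT % y}\n")
    if traj.observables is not None:
        traj.observables.to_csv(out / "observables.tsv", sep="\t", index=False,
                                float_format=FMT)
    summary = build_run_summary(traj)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return out


def _read_frames_xyz(path: Path):
    frames = []
    lines = path.read_text().splitlines()
    pos = 0
    k = -1
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        k += 1
        try:
            natoms = int(lines[pos])
            header = lines[pos + 1]
            fields = dict(item.split("=", 1) for item in header.split() if "=" in item)
            time = float(fields["Time"])
            N, M = int(fields["N"]), int(fields["M"])
            atom_lines = lines[pos + 2: pos + 2 + natoms]
            if len(atom_lines) < natoms:
                raise ValueError("truncated frame")
            coords = np.empty((natoms, 3))
            for idx, line in enumerate(atom_lines):
                parts = line.split()
                coords[idx] = [float(parts[1]), float(parts[2]), float(parts[3])]
            frames.append((time, coords.reshape(N, M, 3)))
            pos += 2 + natoms
        except (ValueError, KeyError, IndexError) as exc:
            raise TrajectoryCorruptionError(f"frames.xyz: {exc}", k - 1) from exc
    return frames


def read_trajectory(indir) -> Trajectory:
    """Read a trajectory directory back into memory (lossless)."""
    ind = Path(indir)
    raw_frames = _read_frames_xyz(ind / "frames.xyz")
    motors_df = pd.read_csv(ind / "motors.tsv", sep="\t")
    wall_df = pd.read_csv(ind / "wall.tsv", sep="\t", float_precision="round_trip")
    obs = pd.read_csv(ind / "observables.tsv", sep="\t", float_precision="round_trip") \
        if (ind / "observables.tsv").exists() else None
    summary = json.loads((ind / "summary.json").read_text()) \
        if (ind / "summary.json").exists() else {}

    params = ModelParams(**summary["params"]) if "params" in summary else None
    frames = []
    for k, (time, positions) in enumerate(raw_frames):
        mot = motors_df[motors_df["frame"] == k][["fil_a", "mon_a", "fil_b", "mon_b"]]
        motors = mot.to_numpy(dtype=np.int64) if len(mot) else np.empty((0, 4), np.int64)
        wn = wall_df[wall_df["frame"] == k]
        wall_nodes = wn[["x", "y"]].to_numpy(dtype=float) if len(wn) else None
        fixed_radius = None
        if wall_nodes is None and obs is not None and k < len(obs):
            fixed_radius = float(obs["R"].iloc[k])
        frames.append(Frame(time, positions, motors, wall_nodes, fixed_radius))
    schedule = None
    if params is not None:
        schedule = Schedule.from_params(params)
    traj = Trajectory(params, schedule, frames, obs)
    traj.final_energy = summary.get("final_energy")
    return traj


def build_run_summary(traj: Trajectory) -> dict:
    """Condense a run into the numbers that place it on a state diagram:
    final state label, vorticity V up to the contraction time, tanh-fit
    parameters, and time-averaged motor statistics."""
    obs = traj.observables
    params = traj.params
    summary: dict = {"version": __version__}
    if params is not None:
        summary["params"] = asdict(params)
        summary["seed"] = params.seed
    if obs is not None and len(obs) >= 2:
        summary["final_state"] = str(obs["state_label"].iloc[-1])
        summary["final_Q"] = [float(obs[f"Q{m}"].iloc[-1]) for m in range(4)]
        t = obs["t"].to_numpy(dtype=float)
        R = obs["R"].to_numpy(dtype=float)
        if len(t) >= 8:
            fit = analysis.fit_contraction(t, R)
            summary["contraction_fit"] = asdict(fit)
            t_cont = fit.t_cont
        else:
            t_cont = t[-1]
        vxp = obs["vxp"].to_numpy(dtype=float)
        finite = np.isfinite(vxp)
        if finite.sum() >= 2:
            mu, sd, V = analysis.vorticity_stats(vxp[finite], t[finite], t_cont)
            summary["vorticity"] = {"mu": mu, "sd": sd, "V": V}
        summary["n_mot_per_fil_mean"] = float(obs["n_mot"].mean() / params.N) \
            if params is not None else float(obs["n_mot"].mean())
        f_plus = obs["f_plus"].to_numpy(dtype=float)
        summary["f_plus_mean"] = float(np.nanmean(f_plus)) \
            if np.isfinite(f_plus).any() else None
    if traj.final_energy is not None:
        summary["final_energy"] = traj.final_energy
    return summary
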