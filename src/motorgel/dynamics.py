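"""Time evolution.

Monomers follow overdamped Brownian dynamics with a local anisotropic
mobility (drag gamma along the filament tangent, 2*gamma perpendicular to
it, the slender-body 2:1 ratio) and thermal noise satisfying
fluctuation-dissipation for that mobility.  Wall nodes move by Metropolis
Monte Carlo in the x-y plane against the wall elastic energy, the
wall-monomer repulsion and a PV term.  ``run_simulation`` interleaves BD
steps, motor-kinetics sweeps and wall sweeps on a fixed schedule; in
fixed-volume mode the wall is a rigid analytic circle following an imposed
radius schedule and no wall moves are attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import mechanics
from .motors import KineticsReport, kinetics_sweep
from .neighbors import PairList, build_pair_list
from .params import ModelParams
from .state import SystemState, init_configuration

__all__ = [
    "Schedule", "Frame", "Trajectory",
    "filament_tangents", "mobility_apply", "bd_step",
    "wall_mc_sweep", "run_simulation",
]

#: verlet skin for the shared neighbour list, in units of b
NEIGHBOR_SKIN = 0.5


class IntegrationError(RuntimeError):
    pass


@dataclass
class Schedule:
    """Update cadence of one run.

    ``radius_schedule`` (fixed-volume mode only) is a list of
    ``(time, radius)`` pairs; the imposed rigid-wall radius is the value of
    the latest entry at or before the current time, R0 before the first.
    """

    dt: float
    kinetics_interval: int = 10
    wall_interval: int = 10
    frame_interval: int = 1000
    t_end: float = 10.0
    radius_schedule: Optional[List[Tuple[float, float]]] = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        for key in ("kinetics_interval", "wall_interval", "frame_interval"):
            if getattr(self, key) < 1:
                raise ValueError(f"{key} must be >= 1")
        if self.radius_schedule is not None:
            times = [t for t, _ in self.radius_schedule]
            if sorted(times) != times:
                raise ValueError("radius_schedule times must be increasing")

    @classmethod
    def from_params(cls, params: ModelParams, frame_interval: Optional[int] = None,
                    radius_schedule=None) -> "Schedule":
        if frame_interval is None:
            # ~4 frames per tau_b by default
            frame_interval = max(1, int(round(0.25 * params.tau_b / params.dt)))
        return cls(
            dt=params.dt,
            kinetics_interval=params.kinetics_interval,
            wall_interval=params.wall_interval,
            frame_interval=frame_interval,
            t_end=params.t_end,
            radius_schedule=radius_schedule,
        )

    def imposed_radius(self, t: float, R0: float) -> float:
        R = R0
        if self.radius_schedule:
            for t_sw, r_sw in self.radius_schedule:
                if t >= t_sw - 1e-12:
                    R = r_sw
        return R


@dataclass
class Frame:
    time: float
    positions: np.ndarray
    motors: np.ndarray
    wall_nodes: Optional[np.ndarray] = None
    fixed_radius: Optional[float] = None


@dataclass
class Trajectory:
    """Time-ordered frames plus per-frame observable records."""

    params: ModelParams
    schedule: Schedule
    frames: List[Frame] = field(default_factory=list)
    observables: Optional["pandas.DataFrame"] = None  # noqa: F821
    final_energy: Optional[dict] = None

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def com_xy(self) -> np.ndarray:
        """Filament centres of mass, (n_frames, N, 2)."""
        return np.stack([f.positions[..., :2].mean(axis=1) for f in self.frames])

    def polarities_xy(self) -> np.ndarray:
        from .analysis import polarities
        return np.stack([polarities(f.positions) for f in self.frames])

    def centers(self) -> np.ndarray:
        """System centre per frame (mean of wall nodes, or the origin)."""
        out = np.zeros((len(self.frames), 2))
        for k, f in enumerate(self.frames):
            if f.wall_nodes is not None:
                out[k] = f.wall_nodes.mean(axis=0)
        return out


# ---------------------------------------------------------------- mobility

def filament_tangents(positions: np.ndarray) -> np.ndarray:
    """Per-monomer unit tangent: normalised mean of the adjacent bond
    directions (single bond at the ends).  Degenerate rows come back as
    zero vectors; callers fall back to isotropic drag there."""
    pos = np.asarray(positions, dtype=float)
    bond = pos[..., 1:, :] - pos[..., :-1, :]
    norm = np.linalg.norm(bond, axis=-1, keepdims=True)
    u = np.divide(bond, norm, out=np.zeros_like(bond), where=norm > 1e-12)
    t = np.zeros_like(pos)
    t[..., 0, :] = u[..., 0, :]
    t[..., -1, :] = u[..., -1, :]
    if pos.shape[-2] > 2:
        t[..., 1:-1, :] = u[..., :-1, :] + u[..., 1:, :]
    tn = np.linalg.norm(t, axis=-1, keepdims=True)
    return np.divide(t, tn, out=np.zeros_like(t), where=tn > 1e-12)


def mobility_apply(positions: np.ndarray, forces: np.ndarray, gamma: float,
                   tangents: Optional[np.ndarray] = None) -> np.ndarray:
    """Apply the anisotropic mobility M = tt/gamma + (I-tt)/(2 gamma).

    A force along the local tangent moves at F/gamma, a perpendicular force
    at F/(2 gamma).  Monomers with a degenerate tangent get isotropic
    1/(2 gamma)."""
    t = filament_tangents(positions) if tangents is None else tangents
    f_par = np.sum(t * forces, axis=-1, keepdims=True) * t
    return f_par / gamma + (forces - f_par) / (2.0 * gamma)


def bd_step(state: SystemState, params: ModelParams, dt: float,
            rng: np.random.Generator, pair_list: Optional[PairList] = None,
            forces: Optional[np.ndarray] = None) -> None:
    """One overdamped step: r += M F dt + xi, <xi xi> = 2 kBT M dt."""
    if forces is None:
        forces = mechanics.total_forces(state, params, pair_list)
    t = filament_tangents(state.positions)
    drift = mobility_apply(state.positions, forces, params.gamma, tangents=t) * dt
    g = rng.standard_normal(state.positions.shape)
    g_par = np.sum(t * g, axis=-1, keepdims=True) * t
    amp = np.sqrt(2.0 * params.kBT * dt)
    xi = amp * (g_par / np.sqrt(params.gamma)
                + (g - g_par) / np.sqrt(2.0 * params.gamma))
    disp = drift + xi
    if not np.all(np.isfinite(disp)):
        bad = np.argwhere(~np.isfinite(disp).all(axis=-1))
        raise IntegrationError(
            f"non-finite displacement at t={state.time:.6g} for (filament, monomer) {bad[0]}"
        )
    state.positions += disp
    state.time += dt


# ---------------------------------------------------------------- wall MC

#: half-window of wall segments scanned for monomer-wall distances around a
#: trial node; exact for near-circular walls where remote segments sit well
#: beyond the WCA cutoff
_SEG_WINDOW = 6


def _local_wall_energy(n5x, n5y, l0: float, kappa0: float, params) -> float:
    """Elastic energy of the 2 edges and 3 turning angles around node n5[2].

    Scalar math on the 5-node neighbourhood (lists of x and y coords); the
    remaining edges and angles are unchanged by a single-node move.
    """
    ex = [n5x[k + 1] - n5x[k] for k in range(4)]
    ey = [n5y[k + 1] - n5y[k] for k in range(4)]
    ln = [math.hypot(ex[k], ey[k]) for k in range(4)]
    stretch = ((ln[1] - l0) ** 2 + (ln[2] - l0) ** 2)
    bend = 0.0
    for k in range(3):   # turning angles at nodes n5[1..3]
        cross = ex[k] * ey[k + 1] - ey[k] * ex[k + 1]
        dot = ex[k] * ex[k + 1] + ey[k] * ey[k + 1]
        dk = math.atan2(cross, dot) / l0 - kappa0
        bend += dk * dk
    return (params.c_stretch * params.kBT * params.Z * stretch / l0 ** 3
            + params.c_bend * params.kBT * l0 * params.Z * bend)


def _local_area2(nodes: np.ndarray, i: int, pos_i: np.ndarray) -> float:
    """Twice the signed-area contribution of the two edges touching node i."""
    n = len(nodes)
    a, b = nodes[(i - 1) % n], nodes[(i + 1) % n]
    return (a[0] * pos_i[1] - pos_i[0] * a[1]) + (pos_i[0] * b[1] - b[0] * pos_i[1])


def _monomer_wall_energy(xy: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray, params) -> float:
    """WCA energy of monomers against the nearest point of a segment set."""
    if len(xy) == 0:
        return 0.0
    p = xy[:, None, :]
    e = (seg_b - seg_a)[None, :, :]
    a = seg_a[None, :, :]
    ee = np.sum(e * e, axis=-1)
    t = np.clip(np.sum((p - a) * e, axis=-1) / np.maximum(ee, 1e-300), 0.0, 1.0)
    diff = p - (a + t[..., None] * e)
    d2 = np.min(np.sum(diff * diff, axis=-1), axis=1)
    d2 = np.maximum(d2, 1e-12)
    inside = d2 < params.wca_cutoff ** 2
    if not np.any(inside):
        return 0.0
    energy, _ = mechanics._wca_subset(d2[inside], params.eps, params.sigma)
    return float(np.sum(energy))


def wall_mc_sweep(state: SystemState, params: ModelParams,
                  rng: np.random.Generator) -> float:
    """One Metropolis sweep over wall nodes; returns the acceptance fraction.

    Each node is attempted once in random order with a trial displacement
    uniform in [-delta_w, delta_w]^2; the move energy is the change in wall
    elastic energy, wall-monomer repulsion and P*V.
    """
    wall = state.wall
    if wall is None:
        raise RuntimeError("wall MC requires pressure mode (elastic wall present)")
    nodes = wall.nodes
    n = len(nodes)
    N, M, _ = state.positions.shape
    mono_xy = state.positions[..., :2].reshape(N * M, 2)
    # candidate radius: a monomer this close to a node can feel the moved edges
    r_cand = wall.l0 + params.wca_cutoff + params.delta_w + 0.5
    # node-monomer candidate lists, computed once per sweep (monomers are
    # frozen during the sweep; node drift ~delta_w is inside the margin)
    d2 = (np.sum(mono_xy ** 2, axis=1)[None, :]
          - 2.0 * nodes @ mono_xy.T
          + np.sum(nodes ** 2, axis=1)[:, None])
    cand_rows = [np.nonzero(row < r_cand ** 2)[0] for row in d2]
    accepted = 0
    order = rng.permutation(n)
    offsets = np.arange(-_SEG_WINDOW, _SEG_WINDOW)
    PZ_half = params.P * params.Z * 0.5
    nx, ny = nodes[:, 0], nodes[:, 1]
    for i in order:
        trial = rng.uniform(-params.delta_w, params.delta_w, size=2)
        ox, oy = nodes[i]
        px, py = ox + trial[0], oy + trial[1]

        k5 = [(i + o) % n for o in (-2, -1, 0, 1, 2)]
        x5 = [nx[k] for k in k5]
        y5 = [ny[k] for k in k5]
        e_old = _local_wall_energy(x5, y5, wall.l0, wall.kappa0, params)
        x5[2], y5[2] = px, py
        dE = _local_wall_energy(x5, y5, wall.l0, wall.kappa0, params) - e_old

        if PZ_half:
            ax, ay = nx[(i - 1) % n], ny[(i - 1) % n]
            bx, by = nx[(i + 1) % n], ny[(i + 1) % n]
            dA2 = ((ax * py - px * ay) + (px * by - bx * py)
                   - (ax * oy - ox * ay) - (ox * by - bx * oy))
            dE += PZ_half * dA2

        cand = cand_rows[i]
        if len(cand):
            seg_idx = (i + offsets) % n
            a_old = nodes[seg_idx]
            b_old = nodes[(seg_idx + 1) % n]
            e_w_old = _monomer_wall_energy(mono_xy[cand], a_old, b_old, params)
            a_new, b_new = a_old.copy(), b_old.copy()
            a_new[seg_idx == i] = (px, py)
            b_new[(seg_idx + 1) % n == i] = (px, py)
            e_w_new = _monomer_wall_energy(mono_xy[cand], a_new, b_new, params)
            dE += e_w_new - e_w_old

        if dE <= 0 or rng.random() < math.exp(-dE / params.kBT):
            nodes[i] = (px, py)
            accepted += 1
    return accepted / n


# ---------------------------------------------------------------- driver

def run_simulation(params: ModelParams, schedule: Optional[Schedule] = None,
                   store_frames: bool = True,
                   n_bins: Optional[int] = None) -> Trajectory:
    """Run one simulation, fully reproducible from ``params.seed``.

    Four independent RNG streams (initial condition, BD noise, motor
    kinetics, wall MC) are spawned from the seed so that altering one
    subsystem's draws cannot perturb the others.  Per-frame observables
    (system radius R, motor counts, mode amplitudes Q0..Q3, state label,
    transverse velocity between stored frames) are collected in
    ``trajectory.observables``.
    """
    from . import analysis  # deferred to avoid an import cycle
    import pandas as pd

    if schedule is None:
        schedule = Schedule.from_params(params)
    if n_bins is None:
        # keep ~4 filaments per angular bin so empty bins stay rare
        n_bins = min(40, max(8, params.N // 4))
    ss = np.random.SeedSequence(params.seed)
    rng_init, rng_bd, rng_kin, rng_wall = (np.random.default_rng(s) for s in ss.spawn(4))

    state = init_configuration(params, rng_init)
    fixed_mode = params.volume_mode == "fixed"
    if fixed_mode:
        state.fixed_radius = schedule.imposed_radius(0.0, params.R0)

    n_steps = int(round(schedule.t_end / schedule.dt))
    pair_list = build_pair_list(state.positions, params.wca_cutoff, NEIGHBOR_SKIN)
    dt_k = schedule.kinetics_interval * schedule.dt

    frames: List[Frame] = []
    records: List[dict] = []
    prev_com = None
    prev_time = None
    v_scale = params.b / params.tau_b

    def record(step_idx: int) -> None:
        nonlocal prev_com, prev_time
        com = state.positions[..., :2].mean(axis=1)
        pol = analysis.polarities(state.positions)
        center = state.center
        modes = analysis.mode_amplitudes(com, pol, center=center, n_bins=n_bins)
        label = analysis.classify_state(modes.Q)
        n_mot = state.n_mot
        from .motors import count_plus_end_motors
        n_plus = count_plus_end_motors(state.motors, params.M)
        if prev_com is not None:
            dt_f = state.time - prev_time
            v = (com - prev_com) / dt_f
            with np.errstate(invalid="ignore"):
                cross = v[:, 0] * pol[:, 1] - v[:, 1] * pol[:, 0]
            vxp = float(np.nanmean(cross)) / v_scale
        else:
            vxp = np.nan
        records.append({
            "t": state.time,
            "t_over_tau_b": state.time / params.tau_b,
            "R": state.radius(),
            "n_mot": n_mot,
            "f_plus": n_plus / n_mot if n_mot else np.nan,
            "Q0": modes.Q[0], "Q1": modes.Q[1], "Q2": modes.Q[2], "Q3": modes.Q[3],
            "state_label": label,
            "vxp": vxp,
        })
        if store_frames:
            frames.append(Frame(
                state.time, state.positions.copy(), state.motors.copy(),
                state.wall.nodes.copy() if state.wall is not None else None,
                state.fixed_radius,
            ))
        prev_com, prev_time = com, state.time

    record(0)
    for step in range(1, n_steps + 1):
        if step % schedule.kinetics_interval == 0:
            pair_list = build_pair_list(state.positions, params.wca_cutoff, NEIGHBOR_SKIN)
            if params.k_A > 0 or state.n_mot:
                kinetics_sweep(state, params, dt_k, rng_kin, pair_list)
        bd_step(state, params, schedule.dt, rng_bd, pair_list)
        if fixed_mode:
            state.fixed_radius = schedule.imposed_radius(state.time, params.R0)
        elif step % schedule.wall_interval == 0:
            wall_mc_sweep(state, params, rng_wall)
        if step % schedule.frame_interval == 0 or step == n_steps:
            record(step)

    traj = Trajectory(params, schedule, frames, pd.DataFrame(records))
    traj.final_energy = mechanics.energy_breakdown(state, params).as_dict()
    return traj
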