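"""Stochastic motor kinetics.

Motors are two-headed springs connecting monomers on different filaments.
Four rates drive the kinetics: attachment ``k_A`` (per eligible monomer
pair within the capture radius — k_A is the product of a molecular rate and
the free-motor concentration, so the free pool never depletes), detachment
``k_D`` per head, stepping ``k_M`` per head towards the [+]-end (monomer
M-1) attenuated by the Boltzmann factor exp(-dE/kBT) of the trial spring
energy change, and end-detachment ``k_E`` which replaces ``k_D`` for heads
sitting at a [+]-end.  Either head detaching removes the whole motor.

Each sweep converts a rate k into a per-event probability 1 - exp(-k*dt_k)
(exact for independent exponential waiting times within the sweep interval
dt_k), except stepping which uses min(1, k_M*dt_k*exp(-dE/kBT)) so the
energetic attenuation acts multiplicatively as specified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neighbors import PairList, build_pair_list
from .state import SystemState, empty_motors

__all__ = [
    "KineticsReport",
    "attempt_attachments",
    "attempt_moves",
    "attempt_detachments",
    "kinetics_sweep",
    "count_plus_end_motors",
]


@dataclass
class KineticsReport:
    n_attached: int = 0
    n_detached: int = 0
    n_moved: int = 0
    n_end_detached: int = 0
    n_mot: int = 0
    n_mot_plus: int = 0

    def merge(self, other: "KineticsReport") -> "KineticsReport":
        return KineticsReport(
            self.n_attached + other.n_attached,
            self.n_detached + other.n_detached,
            self.n_moved + other.n_moved,
            self.n_end_detached + other.n_end_detached,
            other.n_mot,
            other.n_mot_plus,
        )


def count_plus_end_motors(motors: np.ndarray, M: int) -> int:
    """Motors with at least one head at a [+]-end (monomer M-1)."""
    if len(motors) == 0:
        return 0
    return int(np.sum((motors[:, 1] == M - 1) | (motors[:, 3] == M - 1)))


def _report(state: SystemState, M: int, **kw) -> KineticsReport:
    return KineticsReport(
        n_mot=state.n_mot, n_mot_plus=count_plus_end_motors(state.motors, M), **kw
    )


def attempt_attachments(
    state: SystemState, params, dt_k: float, rng: np.random.Generator,
    pair_list: PairList | None = None,
) -> KineticsReport:
    """Spawn motors on monomer pairs (different filaments) within the
    capture radius, each independently with probability 1-exp(-k_A*dt_k).
    Multiple motors may share a monomer."""
    if dt_k <= 0:
        raise ValueError("dt_k must be > 0")
    M = state.positions.shape[1]
    if params.k_A <= 0:
        return _report(state, M)
    if pair_list is None:
        pair_list = build_pair_list(state.positions, params.attach_range, skin=0.0)
    fa, ma, fb, mb = pair_list.unpack()
    different = fa != fb
    fa, ma, fb, mb = fa[different], ma[different], fb[different], mb[different]
    if len(fa) == 0:
        return _report(state, M)
    ra = state.positions[fa, ma]
    rb = state.positions[fb, mb]
    close = np.linalg.norm(ra - rb, axis=1) < params.attach_range
    fa, ma, fb, mb = fa[close], ma[close], fb[close], mb[close]
    if len(fa) == 0:
        return _report(state, M)
    p_attach = 1.0 - np.exp(-params.k_A * dt_k)
    hit = rng.random(len(fa)) < p_attach
    n_new = int(np.sum(hit))
    if n_new:
        new = np.stack([fa[hit], ma[hit], fb[hit], mb[hit]], axis=1).astype(np.int64)
        state.motors = np.concatenate([state.motors, new], axis=0)
    return _report(state, M, n_attached=n_new)


def _move_pass(state: SystemState, params, dt_k, rng, which_head: np.ndarray, sel: np.ndarray):
    """Attempt one step towards the [+]-end for head ``which_head`` of the
    selected motors; returns the number of accepted steps."""
    M = state.positions.shape[1]
    m = state.motors
    col = np.where(which_head[sel] == 0, 1, 3)          # monomer column of the head
    fil_col = col - 1
    rows = np.nonzero(sel)[0]
    mon = m[rows, col]
    movable = mon < M - 1                               # [+]-end heads never move
    rows, col, fil_col, mon = rows[movable], col[movable], fil_col[movable], mon[movable]
    if len(rows) == 0:
        return 0
    fil = m[rows, fil_col]
    other_col = np.where(col == 1, 3, 1)
    r_other = state.positions[m[rows, other_col - 1], m[rows, other_col]]
    r_now = state.positions[fil, mon]
    r_trial = state.positions[fil, mon + 1]
    e_now = 0.5 * params.k_motor * np.sum((r_now - r_other) ** 2, axis=1)
    e_trial = 0.5 * params.k_motor * np.sum((r_trial - r_other) ** 2, axis=1)
    dE = (e_trial - e_now) / params.kBT
    p = np.minimum(1.0, params.k_M * dt_k * np.exp(-dE))
    accept = rng.random(len(rows)) < p
    state.motors[rows[accept], col[accept]] = mon[accept] + 1
    return int(np.sum(accept))


def attempt_moves(
    state: SystemState, params, dt_k: float, rng: np.random.Generator
) -> KineticsReport:
    """Each head steps one monomer towards the [+]-end with probability
    min(1, k_M*dt_k*exp(-dE/kBT)).  Within a motor the two heads are
    processed in random order (heads of distinct motors are independent at
    frozen monomer positions, so any interleaving is equivalent)."""
    M = state.positions.shape[1]
    n = state.n_mot
    if n == 0 or params.k_M <= 0:
        return _report(state, M)
    first = rng.integers(0, 2, size=n)                  # which head of each motor goes first
    moved = _move_pass(state, params, dt_k, rng, first, np.ones(n, dtype=bool))
    moved += _move_pass(state, params, dt_k, rng, 1 - first, np.ones(n, dtype=bool))
    return _report(state, M, n_moved=moved)


def attempt_detachments(
    state: SystemState, params, dt_k: float, rng: np.random.Generator
) -> KineticsReport:
    """Each head detaches with probability 1-exp(-k*dt_k), k = k_E at a
    [+]-end and k_D elsewhere; any detachment removes the whole motor."""
    M = state.positions.shape[1]
    n = state.n_mot
    if n == 0:
        return _report(state, M)
    mons = state.motors[:, [1, 3]]
    at_end = mons == M - 1
    rate = np.where(at_end, params.k_E, params.k_D)
    p = 1.0 - np.exp(-rate * dt_k)
    det = rng.random((n, 2)) < p
    gone = det.any(axis=1)
    n_end = int(np.sum(det & at_end))
    n_gone = int(np.sum(gone))
    if n_gone:
        state.motors = state.motors[~gone]
    return _report(state, M, n_detached=n_gone, n_end_detached=n_end)


def kinetics_sweep(
    state: SystemState, params, dt_k: float, rng: np.random.Generator,
    pair_list: PairList | None = None,
) -> KineticsReport:
    """One full kinetics sweep: attachments, moves, then detachments."""
    rep = attempt_attachments(state, params, dt_k, rng, pair_list)
    rep = rep.merge(attempt_moves(state, params, dt_k, rng))
    rep = rep.merge(attempt_detachments(state, params, dt_k, rng))
    return rep
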