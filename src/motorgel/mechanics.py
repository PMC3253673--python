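"""Potential energies and analytic forces.

Terms: Hookean bonds, discrete worm-like-chain bending, WCA (purely
repulsive, truncated-shifted Lennard-Jones) excluded volume and wall
repulsion, zero-rest-length motor springs, and the elastic energy plus PV
term of the pressurised side wall.  Every force is the exact negative
gradient of its energy (checked by finite differences in the test suite).

The bending discretisation ``(kappa/b) * sum(1 - t_i . t_{i+1})`` over unit
bond vectors gives a 3D persistence length ``l_p = kappa/k_BT``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neighbors import PairList, build_pair_list
from .state import SystemState, WallState

__all__ = [
    "EnergyBreakdown",
    "pair_repulsion",
    "filament_internal",
    "nonbonded_forces",
    "motor_spring",
    "wall_elastic",
    "enclosed_volume",
    "polygon_is_simple",
    "point_to_polygon",
    "energy_breakdown",
]


class DegenerateGeometryError(RuntimeError):
    pass


@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    bend: float = 0.0
    excluded_volume: float = 0.0
    z_walls: float = 0.0
    side_wall: float = 0.0
    motor_springs: float = 0.0
    wall_stretch: float = 0.0
    wall_bend: float = 0.0
    pressure_volume: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.bond + self.bend + self.excluded_volume + self.z_walls
            + self.side_wall + self.motor_springs + self.wall_stretch
            + self.wall_bend + self.pressure_volume
        )

    def as_dict(self) -> dict:
        d = {k: float(v) for k, v in self.__dict__.items()}
        d["total"] = self.total
        return d


# ---------------------------------------------------------------- WCA

def pair_repulsion(r, eps: float, sigma: float):
    """WCA energy and repulsive force magnitude at separation ``r``.

    ``E(r) = 4*eps*[(sigma/r)^12 - (sigma/r)^6] + eps`` for
    ``r < 2^(1/6)*sigma``, zero beyond; the returned force is ``-dE/dr``
    (positive = repulsive).  Scalar or array ``r``; requires ``r > 0``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair_repulsion requires r > 0")
    cutoff = 2.0 ** (1.0 / 6.0) * sigma
    inside = r < cutoff
    sr6 = np.where(inside, (sigma / np.where(inside, r, cutoff)) ** 6, 0.0)
    energy = np.where(inside, 4.0 * eps * (sr6 * sr6 - sr6) + eps, 0.0)
    force = np.where(inside, 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r, 0.0)
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


# ---------------------------------------------------------------- filaments

def filament_internal(positions: np.ndarray, k_bond: float, kappa: float, b: float):
    """Bond + bending energy and forces for one or many filaments.

    ``positions`` is (M, 3) or (..., M, 3).  Returns
    ``(E_bond, E_bend, forces)`` with forces of the same shape.
    Bond: ``0.5*k_bond*sum((l_i - b)^2)``;
    bend: ``(kappa/b)*sum(1 - u_i . u_{i+1})`` over interior joints.
    """
    pos = np.asarray(positions, dtype=float)
    single = pos.ndim == 2
    if single:
        pos = pos[None]
    if pos.shape[-2] < 2:
        raise ValueError("filament needs at least 2 monomers")

    bond_vec = pos[..., 1:, :] - pos[..., :-1, :]          # (..., M-1, 3)
    length = np.linalg.norm(bond_vec, axis=-1)             # (..., M-1)
    if np.any(length < 1e-12):
        raise DegenerateGeometryError("coincident consecutive monomers (zero bond vector)")
    u = bond_vec / length[..., None]

    stretch = length - b
    e_bond = 0.5 * k_bond * float(np.sum(stretch ** 2))
    # dE/d(bond_vec_j) for the bond term
    dEdb = k_bond * stretch[..., None] * u

    e_bend = 0.0
    if pos.shape[-2] >= 3:
        c = np.sum(u[..., :-1, :] * u[..., 1:, :], axis=-1)          # (..., M-2)
        e_bend = (kappa / b) * float(np.sum(1.0 - c))
        # d(u_j.u_{j+1})/d(bond_vec_j) and /d(bond_vec_{j+1})
        g1 = (u[..., 1:, :] - c[..., None] * u[..., :-1, :]) / length[..., :-1, None]
        g2 = (u[..., :-1, :] - c[..., None] * u[..., 1:, :]) / length[..., 1:, None]
        dEdb[..., :-1, :] -= (kappa / b) * g1
        dEdb[..., 1:, :] -= (kappa / b) * g2

    forces = np.zeros_like(pos)
    forces[..., :-1, :] += dEdb
    forces[..., 1:, :] -= dEdb
    if single:
        forces = forces[0]
    return e_bond, e_bend, forces


# ---------------------------------------------------------------- walls

def point_to_polygon(points_xy: np.ndarray, nodes: np.ndarray):
    """Distance from each 2D point to the nearest point of a closed polygon.

    Returns ``(dist, away)`` where ``away`` is the unit vector from the
    closest boundary point towards the query point (zero where dist = 0).
    """
    p = np.atleast_2d(points_xy)[:, None, :]               # (n, 1, 2)
    a = nodes[None, :, :]                                  # (1, m, 2)
    e = np.roll(nodes, -1, axis=0)[None, :, :] - a         # segment vectors
    ee = np.sum(e * e, axis=-1)
    t = np.clip(np.sum((p - a) * e, axis=-1) / np.maximum(ee, 1e-300), 0.0, 1.0)
    proj = a + t[..., None] * e                            # (n, m, 2)
    diff = p - proj
    d2 = np.sum(diff * diff, axis=-1)
    k = np.argmin(d2, axis=1)
    idx = np.arange(len(k))
    dist = np.sqrt(d2[idx, k])
    away = diff[idx, k] / np.maximum(dist, 1e-300)[:, None]
    return dist, away


def _side_wall_terms(state: SystemState, params):
    """Side-wall WCA energy and in-plane forces on monomers."""
    N, M, _ = state.positions.shape
    xy = state.positions[..., :2].reshape(N * M, 2)
    forces = np.zeros((N * M, 3))
    if state.wall is None and state.fixed_radius is None:
        return 0.0, forces.reshape(N, M, 3)     # unconfined in-plane
    if state.wall is not None:
        center = state.wall.center
        # prefilter: only monomers radially within reach of the polygon
        r_node = np.linalg.norm(state.wall.nodes - center, axis=1)
        r_mon = np.linalg.norm(xy - center, axis=1)
        cand = np.nonzero(r_mon > r_node.min() - params.wca_cutoff - 1.0)[0]
        if len(cand) == 0:
            return 0.0, forces.reshape(N, M, 3)
        dist, away = point_to_polygon(xy[cand], state.wall.nodes)
    else:
        # rigid circle of imposed radius about the origin
        R = state.fixed_radius
        r_mon = np.linalg.norm(xy, axis=1)
        cand = np.arange(N * M)
        dist = R - r_mon
        away = -xy / np.maximum(r_mon, 1e-300)[:, None]
    # monomers outside the rigid circle (dist <= 0) or overlapping the wall
    # fall into the linearised deep-overlap branch: a capped push along `away`
    dist = np.maximum(dist, 1e-6)
    near = np.nonzero(dist < params.wca_cutoff)[0]
    energy = 0.0
    if len(near):
        e, f_over_r = _wca_subset(dist[near] ** 2, params.eps, params.sigma)
        energy = float(np.sum(e))
        forces[cand[near], :2] = (f_over_r * dist[near])[:, None] * away[near]
    return energy, forces.reshape(N, M, 3)


#: deep-overlap guard: below this fraction of sigma the WCA potential is
#: continued linearly (constant repulsive force), capping the push from
#: rare overlaps (e.g. monomers caught outside a suddenly reduced rigid
#: wall) at a finite value the integrator can absorb; configurations this
#: deep are Boltzmann-suppressed by >15 kBT so equilibrium properties are
#: unaffected, and the linearised energy keeps force = -grad E exact
_MIN_DIST_FACTOR = 0.9


def _wca_subset(r2: np.ndarray, eps: float, sigma: float):
    """Energy and force/r from squared distances already inside the cutoff.

    Distances below the overlap guard use the linear continuation
    ``E(d) = E(d0) + f(d0) * (d0 - d)`` with ``d0 = 0.9 sigma``.
    """
    d0 = _MIN_DIST_FACTOR * sigma
    r2c = np.maximum(r2, d0 * d0)
    sr6 = (sigma * sigma / r2c) ** 3
    energy = 4.0 * eps * (sr6 * sr6 - sr6) + eps
    f_over_r = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2c
    deep = r2 < d0 * d0
    if np.any(deep):
        sr6_0 = (sigma / d0) ** 6
        e0 = 4.0 * eps * (sr6_0 * sr6_0 - sr6_0) + eps
        f0 = 24.0 * eps * (2.0 * sr6_0 * sr6_0 - sr6_0) / d0
        d = np.sqrt(np.asarray(r2)[deep])
        energy = np.asarray(energy)
        f_over_r = np.asarray(f_over_r)
        energy[deep] = e0 + f0 * (d0 - d)
        f_over_r[deep] = f0 / np.maximum(d, 1e-12)
    return energy, f_over_r


def _z_wall_terms(state: SystemState, params):
    z = state.positions[..., 2].ravel()
    fz = np.zeros_like(z)
    cutoff = params.wca_cutoff
    energy = 0.0
    for d, sgn in ((np.maximum(z, 1e-6), 1.0), (np.maximum(params.Z - z, 1e-6), -1.0)):
        idx = np.nonzero(d < cutoff)[0]
        if len(idx):
            e, f_over_r = _wca_subset(d[idx] ** 2, params.eps, params.sigma)
            energy += float(np.sum(e))
            fz[idx] += sgn * f_over_r * d[idx]
    forces = np.zeros_like(state.positions)
    forces[..., 2] = fz.reshape(state.positions.shape[:2])
    return energy, forces


def nonbonded_forces(state: SystemState, params, pair_list: PairList | None = None):
    """Excluded volume + flat-plate + side-wall repulsion.

    Returns ``(ev_energy, z_energy, side_energy, forces)``; ``forces`` has
    shape (N, M, 3).  ``pair_list`` may be supplied to reuse a neighbour
    list; otherwise one is built on the fly.
    """
    N, M, _ = state.positions.shape
    flat = state.positions.reshape(N * M, 3)
    if pair_list is None:
        pair_list = build_pair_list(state.positions, params.wca_cutoff)
    forces = np.zeros((N * M, 3))
    ev_energy = 0.0
    if len(pair_list.pairs):
        i, j = pair_list.pairs[:, 0], pair_list.pairs[:, 1]
        dvec = flat[i] - flat[j]
        r2 = np.einsum("ij,ij->i", dvec, dvec)
        close = r2 < params.wca_cutoff ** 2
        if np.any(close):
            i, j, dvec = i[close], j[close], dvec[close]
            r2 = np.maximum(r2[close], 1e-12)
            e, f_over_r = _wca_subset(r2, params.eps, params.sigma)
            ev_energy = float(np.sum(e))
            fvec = f_over_r[:, None] * dvec
            n_flat = N * M
            for c in range(3):
                forces[:, c] += np.bincount(i, weights=fvec[:, c], minlength=n_flat)
                forces[:, c] -= np.bincount(j, weights=fvec[:, c], minlength=n_flat)
    forces = forces.reshape(N, M, 3)
    z_energy, fz = _z_wall_terms(state, params)
    side_energy, fs = _side_wall_terms(state, params)
    return ev_energy, z_energy, side_energy, forces + fz + fs


# ---------------------------------------------------------------- motors

def motor_spring(state: SystemState, params):
    """Zero-rest-length Hookean motor springs: energy and monomer forces."""
    forces = np.zeros_like(state.positions)
    if state.n_mot == 0:
        return 0.0, forces
    m = state.motors
    N, M, _ = state.positions.shape
    if m[:, [0, 2]].max() >= N or m[:, [1, 3]].max() >= M or m.min() < 0:
        raise ValueError("motor head references a non-existent monomer")
    ra = state.positions[m[:, 0], m[:, 1]]
    rb = state.positions[m[:, 2], m[:, 3]]
    d = ra - rb
    energy = 0.5 * params.k_motor * float(np.sum(d * d))
    flat = forces.reshape(N * M, 3)
    fa = -params.k_motor * d
    np.add.at(flat, m[:, 0] * M + m[:, 1], fa)
    np.add.at(flat, m[:, 2] * M + m[:, 3], -fa)
    return energy, flat.reshape(N, M, 3)


# ---------------------------------------------------------------- wall

def _wall_geometry(nodes: np.ndarray):
    e = np.roll(nodes, -1, axis=0) - nodes          # edge i: node_i -> node_{i+1}
    lengths = np.linalg.norm(e, axis=1)
    u = e / lengths[:, None]
    u_prev = np.roll(u, 1, axis=0)                  # edge into node i
    cross = u_prev[:, 0] * u[:, 1] - u_prev[:, 1] * u[:, 0]
    dot = np.sum(u_prev * u, axis=1)
    phi = np.arctan2(cross, dot)                    # signed turning angle at node i
    return lengths, phi


def wall_elastic(wall: WallState, params):
    """Stretch + bend energy of the discrete elastic wall.

    Stretch: ``c_stretch*kBT*Z*(l - l0)^2 / l0^3`` per adjacent node pair.
    Bend: ``c_bend*kBT*l0*Z*(kappa_i - kappa0)^2`` per node triplet, with
    discrete curvature ``kappa_i = phi_i / l0`` (phi_i the turning angle).
    """
    if len(wall.nodes) < 3:
        raise ValueError("wall needs at least 3 nodes")
    lengths, phi = _wall_geometry(wall.nodes)
    dl = lengths - wall.l0
    stretch = params.c_stretch * params.kBT * params.Z * float(np.sum(dl * dl)) / wall.l0 ** 3
    dk = phi / wall.l0 - wall.kappa0
    bend = params.c_bend * params.kBT * wall.l0 * params.Z * float(np.sum(dk * dk))
    return stretch, bend


def _signed_area(nodes: np.ndarray) -> float:
    x, y = nodes[:, 0], nodes[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_is_simple(nodes: np.ndarray) -> bool:
    """True if no two non-adjacent edges intersect (O(n^2) diagnostic)."""
    n = len(nodes)
    a = nodes
    b = np.roll(nodes, -1, axis=0)
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j - i) % n == 1 or (i - j) % n == 1:
                continue
            if _segments_intersect(a[i], b[i], a[j], b[j]):
                return False
    return True


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4 and o1 != 0 and o2 != 0


def enclosed_volume(wall: WallState, Z: float, check: bool = False) -> float:
    """Polygon (shoelace) area times the plate gap Z; orientation-free."""
    if check and not polygon_is_simple(wall.nodes):
        raise ValueError("wall polygon is self-intersecting")
    return abs(_signed_area(wall.nodes)) * Z


# ---------------------------------------------------------------- totals

def energy_breakdown(state: SystemState, params, pair_list: PairList | None = None) -> EnergyBreakdown:
    """Full energy budget of a state, in k_BT."""
    eb = EnergyBreakdown()
    e_bond, e_bend, _ = filament_internal(state.positions, params.k_bond, params.kappa, params.b)
    eb.bond, eb.bend = e_bond, e_bend
    eb.excluded_volume, eb.z_walls, eb.side_wall, _ = nonbonded_forces(state, params, pair_list)
    eb.motor_springs, _ = motor_spring(state, params)
    if state.wall is not None:
        eb.wall_stretch, eb.wall_bend = wall_elastic(state.wall, params)
        eb.pressure_volume = params.P * enclosed_volume(state.wall, params.Z)
    return eb


def total_forces(state: SystemState, params, pair_list: PairList | None = None):
    """Sum of all monomer forces (bond, bend, WCA, walls, motors)."""
    _, _, f_int = filament_internal(state.positions, params.k_bond, params.kappa, params.b)
    _, _, _, f_nb = nonbonded_forces(state, params, pair_list)
    _, f_mot = motor_spring(state, params)
    return f_int + f_nb + f_mot
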