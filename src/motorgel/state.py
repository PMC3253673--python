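"""System state containers and initial-configuration construction.

Conventions fixed here and used everywhere: monomer index 0 is a filament's
[-]-end and index ``M-1`` its [+]-end; the wall lives in the x-y plane and the
flat plates at z=0 and z=Z; the system centre is the mean of the wall nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["WallState", "SystemState", "InitialisationError", "init_configuration", "make_wall"]


class InitialisationError(RuntimeError):
    """Raised when a geometrically valid initial configuration cannot be built."""


@dataclass
class WallState:
    """Elastic side wall: a closed polygon of nodes in the x-y plane.

    ``l0`` (reference node spacing) and ``kappa0`` (reference discrete
    curvature, turning angle / l0) are fixed at construction so the elastic
    energy is zero for the initial regular polygon.
    """

    nodes: np.ndarray  # (n_wall, 2)
    l0: float
    kappa0: float

    def copy(self) -> "WallState":
        return WallState(self.nodes.copy(), self.l0, self.kappa0)

    @property
    def center(self) -> np.ndarray:
        return self.nodes.mean(axis=0)

    def mean_radius(self) -> float:
        """Mean node distance from the node centroid — the system radius R."""
        return float(np.linalg.norm(self.nodes - self.center, axis=1).mean())


@dataclass
class SystemState:
    """Coordinates, motor roster and wall at one instant.

    ``positions`` is (N, M, 3); ``motors`` is an integer array of shape
    (n_mot, 4) with columns (fil_a, mon_a, fil_b, mon_b) — the two heads of
    one motor always sit on different filaments and the whole motor is
    removed when either head detaches.  In fixed-volume mode ``wall`` is
    None and ``fixed_radius`` holds the imposed rigid-circle radius.
    """

    positions: np.ndarray                 # (N, M, 3)
    motors: np.ndarray                    # (n_mot, 4) int
    wall: Optional[WallState]
    time: float = 0.0
    fixed_radius: Optional[float] = None

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(),
            self.motors.copy(),
            self.wall.copy() if self.wall is not None else None,
            self.time,
            self.fixed_radius,
        )

    @property
    def n_mot(self) -> int:
        return len(self.motors)

    @property
    def center(self) -> np.ndarray:
        if self.wall is not None:
            return self.wall.center
        return np.zeros(2)

    def radius(self) -> float:
        if self.wall is not None:
            return self.wall.mean_radius()
        if self.fixed_radius is not None:
            return float(self.fixed_radius)
        raise ValueError("state has neither an elastic wall nor a fixed radius")

    def validate(self, M: Optional[int] = None) -> None:
        """Cheap consistency checks; raises ValueError on corruption."""
        if self.motors.size:
            if np.any(self.motors[:, 0] == self.motors[:, 2]):
                raise ValueError("motor with both heads on one filament")
            M_eff = M if M is not None else self.positions.shape[1]
            mons = self.motors[:, [1, 3]]
            if mons.min() < 0 or mons.max() >= M_eff:
                raise ValueError("motor head monomer index out of range")
            fils = self.motors[:, [0, 2]]
            if fils.min() < 0 or fils.max() >= self.positions.shape[0]:
                raise ValueError("motor head filament index out of range")


def empty_motors() -> np.ndarray:
    return np.empty((0, 4), dtype=np.int64)


def make_wall(R0: float, n_wall: int) -> WallState:
    """Regular ``n_wall``-gon of circumradius ``R0``, counter-clockwise."""
    ang = 2.0 * np.pi * np.arange(n_wall) / n_wall
    nodes = R0 * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    l0 = 2.0 * R0 * np.sin(np.pi / n_wall)
    kappa0 = (2.0 * np.pi / n_wall) / l0
    return WallState(nodes, l0, kappa0)


def init_configuration(params, rng: np.random.Generator) -> SystemState:
    """Radial aster initial condition.

    Filaments are straight and radial with [+]-ends pointing inward,
    distributed as evenly as possible over three z-layers at z = b, Z/2 and
    Z - b.  Each filament spans radii [R0 - L - 2b, R0 - 2b] ([-]-end
    outermost).  Azimuthal positions are regular within a layer plus a small
    seeded jitter.  The wall is a regular polygon of radius R0; the motor
    roster starts empty.
    """
    N, M, b = params.N, params.M, params.b
    L, R0 = params.L, params.R0
    r_out = R0 - 2.0 * b
    r_in = r_out - L
    if r_in <= b:
        raise InitialisationError(
            f"filaments of length L={L} do not fit inside R0={R0} with clearance"
        )

    counts = [N // 3] * 3
    for i in range(N - 3 * (N // 3)):
        counts[i] += 1
    z_layers = [b, params.Z / 2.0, params.Z - b]

    positions = np.empty((N, M, 3))
    radial = r_out - b * np.arange(M)  # monomer 0 ([-]-end) outermost
    fil = 0
    for n_layer, z in zip(counts, z_layers):
        base = 2.0 * np.pi * np.arange(n_layer) / max(n_layer, 1)
        jitter = rng.uniform(-0.5, 0.5, size=n_layer) * (2.0 * np.pi / max(n_layer, 1)) * 0.5
        theta = base + jitter + rng.uniform(0.0, 2.0 * np.pi)
        for th in theta:
            c, s = np.cos(th), np.sin(th)
            positions[fil, :, 0] = radial * c
            positions[fil, :, 1] = radial * s
            positions[fil, :, 2] = z
            fil += 1

    if params.volume_mode == "fixed":
        return SystemState(positions, empty_motors(), None, 0.0, fixed_radius=R0)
    return SystemState(positions, empty_motors(), make_wall(R0, params.n_wall), 0.0)
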