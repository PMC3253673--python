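"""Synthetic-data generators.

These emulate the kinematic and statistical signatures the analysis module
measures — ideal polarity fields, rigidly rotating/diffusing rings,
tanh-shaped contraction curves and lifetime samples — without running the
simulator, so every analysis operation is testable in isolation.  All
generators are deterministic given their RNG.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

__all__ = [
    "IDEAL_FIELDS",
    "gen_ideal_field",
    "gen_rotating_ring",
    "gen_tanh_radius",
    "gen_lifetime_sample",
]


def _aster(theta):
    return np.stack([-np.cos(theta), -np.sin(theta)], axis=-1)


def _semi_aster(theta):
    return np.stack([-np.cos(theta / 3.0), -np.sin(theta / 3.0)], axis=-1)


def _spindle(theta):
    return np.stack([-np.cos(theta), np.sin(theta)], axis=-1)


#: (support intervals, polarity function) of each ideal field
IDEAL_FIELDS = {
    "aster": ([(-np.pi, np.pi)], _aster),
    "semi-aster": ([(-0.75 * np.pi, 0.75 * np.pi)], _semi_aster),
    "spindle": ([(-0.25 * np.pi, 0.25 * np.pi), (0.75 * np.pi, 1.25 * np.pi)], _spindle),
    "nematic": ([(-np.pi, np.pi)], None),
}


def _rotate(vectors: np.ndarray, angles: np.ndarray) -> np.ndarray:
    c, s = np.cos(angles), np.sin(angles)
    x, y = vectors[..., 0], vectors[..., 1]
    return np.stack([c * x - s * y, s * x + c * y], axis=-1)


def gen_ideal_field(state_name: str, n: int, noise: float = 0.0,
                    rng: Optional[np.random.Generator] = None,
                    radius: float = 1.0) -> Tuple[np.ndarray, np.ndarray]:
    """Points on a ring carrying an ideal polarity field.

    ``n`` points are placed uniformly in angle over the field's support and
    given the ideal polarity, each rotated by an independent Gaussian angle
    of SD ``noise`` (radians).  The nematic is realised as antiparallel
    pairs of unit polarities (random common axis per pair) so the bin-mean
    orientation vanishes while every filament stays a unit vector.
    Returns ``(positions, polarities)``, both (n, 2).
    """
    if state_name not in IDEAL_FIELDS:
        raise ValueError(f"unknown ideal state {state_name!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng or np.random.default_rng()
    intervals, func = IDEAL_FIELDS[state_name]
    widths = np.array([hi - lo for lo, hi in intervals])
    total = widths.sum()
    # uniform spacing over the support, mapped piecewise to the intervals
    u = (np.arange(n) + 0.5) / n * total
    theta = np.empty(n)
    start = 0.0
    for (lo, hi), w in zip(intervals, widths):
        inside = (u >= start) & (u < start + w)
        theta[inside] = lo + (u[inside] - start)
        start += w
    positions = radius * np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    if state_name == "nematic":
        axis = rng.uniform(0.0, 2.0 * np.pi, size=(n + 1) // 2)
        axis = np.repeat(axis, 2)[:n]
        sign = np.resize([1.0, -1.0], n)
        pol = sign[:, None] * np.stack([np.cos(axis), np.sin(axis)], axis=-1)
    else:
        pol = func(theta)
    if noise > 0:
        pol = _rotate(pol, rng.normal(0.0, noise, size=n))
    return positions, pol


def gen_rotating_ring(omega: float, D_theta: float, n: int, frames: int,
                      dt: float = 1.0, radius: float = 1.0,
                      rng: Optional[np.random.Generator] = None):
    """Trajectory of ``n`` aster-oriented particles on a ring, advancing
    ``omega*dt`` per frame with angular diffusion of coefficient
    ``D_theta`` — a rigid rotor for ``D_theta = 0``, free angular diffusion
    for ``omega = 0``.  Returns ``(times, com_xy, polarity_xy)`` with
    shapes (frames,), (frames, n, 2), (frames, n, 2).
    """
    if frames < 2:
        raise ValueError("need at least 2 frames")
    rng = rng or np.random.default_rng()
    theta0 = 2.0 * np.pi * np.arange(n) / n
    steps = omega * dt + np.sqrt(2.0 * D_theta * dt) * rng.standard_normal((frames - 1, n))
    theta = np.vstack([theta0, theta0 + np.cumsum(steps, axis=0)])
    times = dt * np.arange(frames)
    com = radius * np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    pol = np.stack([-np.cos(theta), -np.sin(theta)], axis=-1)
    return times, com, pol


def gen_tanh_radius(R_min: float, dR: float, t_cont: float, dt_width: float,
                    times: np.ndarray, noise: float = 0.0,
                    rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """R(t) = R_min + dR*tanh[(t - t_cont)/dt_width] plus i.i.d. Gaussian
    noise of SD ``noise``.  Note dR < 0 describes a contracting system."""
    rng = rng or np.random.default_rng()
    t = np.asarray(times, dtype=float)
    r = R_min + dR * np.tanh((t - t_cont) / dt_width)
    if noise > 0:
        r = r + rng.normal(0.0, noise, size=t.shape)
    return r


def gen_lifetime_sample(dist: str, mean: float, n: int,
                        rng: Optional[np.random.Generator] = None,
                        sd: Optional[float] = None) -> np.ndarray:
    """i.i.d. lifetime sample: ``dist`` is "exponential" (constant-rate
    events) or "normal" (fixed-time events, SD defaulting to mean/4)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean <= 0:
        raise ValueError("mean must be > 0")
    rng = rng or np.random.default_rng()
    if dist == "exponential":
        return rng.exponential(mean, size=n)
    if dist == "normal":
        return rng.normal(mean, sd if sd is not None else mean / 4.0, size=n)
    raise ValueError(f"unknown distribution {dist!r}")
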