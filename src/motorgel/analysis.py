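"""Order parameters and run statistics.

The polarity field p(theta) — the mean in-plane filament polarity at
azimuthal angle theta about the system centre — is decomposed into angular
Fourier modes

    p(theta) = a0/(2 pi) + (1/pi) * sum_m [ a_m cos(m theta) + b_m sin(m theta) ],

with 2-vector coefficients a_m = integral p(theta) cos(m theta) dtheta and
b_m likewise with sin.  The rotation-invariant mode amplitudes are

    Q_m = (|a_m|^2 + |b_m|^2) / (2 pi^2),

and a snapshot is classified by the Euclidean-nearest ideal-state target
vector (Q_0..Q_3).  Two target sets are available: the "printed" tuples in
common use, and the "derived" set obtained by direct quadrature of the
ideal fields (the two differ for the spindle Q_1, Q_3 and the semi-aster
Q_2; see docs/methods.md).

Also here: transverse-velocity vorticity, the four-parameter tanh fit that
locates contraction events, mean-squared angular displacement (MSAD),
motor statistics, Anderson-Darling lifetime tests with bootstrap p-values,
the exact binomial rotation-direction test, and switching-time extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .state import SystemState

__all__ = [
    "ModeAmplitudes", "ContractionFit",
    "filament_polarity", "polarities",
    "mode_amplitudes", "mode_amplitudes_from_state",
    "ideal_state_targets", "classify_state", "STATE_ORDER", "VORTEX_THRESHOLD",
    "transverse_velocity", "vorticity_stats", "mean_vorticity",
    "fit_contraction", "msad", "msad_slope",
    "motor_statistics", "anderson_darling", "lifetime_tests",
    "binomial_direction_test", "switching_times",
]

#: fixed label order; also the deterministic tie-break order
STATE_ORDER = ("spindle", "aster", "nematic", "semi-aster")

#: a parameter point is called a vortex when the run-averaged vorticity
#: exceeds this value
VORTEX_THRESHOLD = 0.7


class AnalysisError(RuntimeError):
    pass


# ---------------------------------------------------------------- polarity

def filament_polarity(positions: np.ndarray) -> np.ndarray:
    """Unit x-y projection of the [-]-to-[+] end-to-end vector.

    Returns ``[nan, nan]`` when the projection vanishes (vertical filament);
    such filaments are skipped in averages.
    """
    pos = np.asarray(positions, dtype=float)
    v = pos[-1, :2] - pos[0, :2]
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        return np.array([np.nan, np.nan])
    return v / norm


def polarities(positions: np.ndarray) -> np.ndarray:
    """Vectorised :func:`filament_polarity` over (N, M, 3) -> (N, 2)."""
    pos = np.asarray(positions, dtype=float)
    v = pos[:, -1, :2] - pos[:, 0, :2]
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    out = np.full_like(v, np.nan)
    ok = norm[:, 0] > 1e-12
    out[ok] = v[ok] / norm[ok]
    return out


# ---------------------------------------------------------------- modes

@dataclass
class ModeAmplitudes:
    """Angular Fourier coefficients a_m, b_m (2-vectors, m = 0..3) and the
    rotation-invariant amplitudes Q_0..Q_3 (b_0 is identically zero)."""

    a: np.ndarray   # (4, 2)
    b: np.ndarray   # (4, 2)
    Q: np.ndarray   # (4,)


def mode_amplitudes(com_xy: np.ndarray, polarity_xy: np.ndarray,
                    center: Sequence[float] = (0.0, 0.0),
                    n_bins: int = 40, m_max: int = 3) -> ModeAmplitudes:
    """Mode amplitudes of a snapshot's polarity field.

    ``com_xy`` are filament centre-of-mass x-y positions (N, 2) and
    ``polarity_xy`` the matching unit polarities (N, 2); rows with
    non-finite polarity are skipped.  p(theta) is estimated on ``n_bins``
    equal angular bins about ``center`` as the plain (non-renormalised)
    mean polarity of the filaments in each bin, empty bins contributing
    zero, and the coefficient integrals are evaluated as Riemann sums over
    the bin centres.
    """
    com = np.atleast_2d(np.asarray(com_xy, dtype=float))
    pol = np.atleast_2d(np.asarray(polarity_xy, dtype=float))
    ok = np.isfinite(pol).all(axis=1)
    com, pol = com[ok], pol[ok]
    if len(com) == 0:
        raise AnalysisError("no filaments with defined polarity")
    theta = np.mod(np.arctan2(com[:, 1] - center[1], com[:, 0] - center[0]), 2 * np.pi)
    dth = 2 * np.pi / n_bins
    which = np.minimum((theta / dth).astype(int), n_bins - 1)
    p_bin = np.zeros((n_bins, 2))
    counts = np.bincount(which, minlength=n_bins)
    for c in range(2):
        sums = np.bincount(which, weights=pol[:, c], minlength=n_bins)
        p_bin[:, c] = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    th_c = (np.arange(n_bins) + 0.5) * dth

    m = np.arange(m_max + 1)
    cos_m = np.cos(np.outer(m, th_c))       # (m_max+1, n_bins)
    sin_m = np.sin(np.outer(m, th_c))
    a = cos_m @ p_bin * dth                 # (m_max+1, 2)
    b = sin_m @ p_bin * dth
    b[0] = 0.0
    Q = (np.sum(a * a, axis=1) + np.sum(b * b, axis=1)) / (2.0 * np.pi ** 2)
    return ModeAmplitudes(a, b, Q)


def mode_amplitudes_from_state(state: SystemState, n_bins: int = 40) -> ModeAmplitudes:
    com = state.positions[..., :2].mean(axis=1)
    return mode_amplitudes(com, polarities(state.positions),
                           center=state.center, n_bins=n_bins)


def ideal_state_targets(source: str = "printed") -> Dict[str, np.ndarray]:
    """Target (Q_0..Q_3) vectors for the four ideal states.

    ``source="printed"`` returns the tuples in common circulation;
    ``source="derived"`` returns values from direct quadrature of the ideal
    fields — aster p = (-cos t, -sin t) on the full circle; nematic p = 0;
    spindle p = (-cos t, sin t) on (-pi/4, pi/4) u (3pi/4, 5pi/4); semi-aster
    p = (-cos(t/3), -sin(t/3)) on (-3pi/4, 3pi/4).  The sets differ in the
    spindle Q_1, Q_3 (printed = 2x derived) and the semi-aster Q_2
    denominator; classification defaults to "printed".
    """
    pi2 = np.pi ** 2
    if source == "printed":
        return {
            "spindle": np.array([0.0, 2.0 / pi2 + 0.5, 0.0, 2.0 / pi2]),
            "aster": np.array([0.0, 1.0, 0.0, 0.0]),
            "nematic": np.zeros(4),
            "semi-aster": np.array([9.0 / pi2, 9.0 / (4 * pi2),
                                    333.0 / (1715.0 * pi2), 9.0 / (100 * pi2)]),
        }
    if source == "derived":
        return {
            "spindle": np.array([0.0, 0.25 + 1.0 / pi2, 0.0, 1.0 / pi2]),
            "aster": np.array([0.0, 1.0, 0.0, 0.0]),
            "nematic": np.zeros(4),
            "semi-aster": np.array([9.0 / pi2, 9.0 / (4 * pi2),
                                    333.0 / (1225.0 * pi2), 9.0 / (100 * pi2)]),
        }
    raise ValueError(f"unknown target source {source!r}")


def classify_state(Q: np.ndarray, targets: Optional[Dict[str, np.ndarray]] = None) -> str:
    """Label of the Euclidean-nearest ideal target; ties break in the fixed
    order spindle, aster, nematic, semi-aster."""
    if targets is None:
        targets = ideal_state_targets("printed")
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (4,):
        raise ValueError("Q must have 4 components")
    best, best_d = None, np.inf
    for label in STATE_ORDER:
        if label not in targets:
            continue
        d = float(np.linalg.norm(Q - targets[label]))
        if d < best_d - 1e-15:
            best, best_d = label, d
    return best


# ---------------------------------------------------------------- vorticity

def transverse_velocity(times: np.ndarray, com_xy: np.ndarray,
                        polarity_xy: np.ndarray, v_scale: float = 1.0) -> np.ndarray:
    """Filament-averaged transverse velocity series <(v x p)_z> / v_scale.

    ``com_xy`` and ``polarity_xy`` are (n_frames, N, 2).  Velocities use
    centred finite differences (one-sided at the series ends); the scalar
    cross product is ``v_x p_y - v_y p_x``.  Filaments with undefined
    polarity at a frame are skipped in that frame's average.
    """
    times = np.asarray(times, dtype=float)
    com = np.asarray(com_xy, dtype=float)
    if len(times) < 2:
        raise AnalysisError("need at least 2 frames")
    v = np.gradient(com, times, axis=0)
    cross = v[..., 0] * polarity_xy[..., 1] - v[..., 1] * polarity_xy[..., 0]
    with np.errstate(invalid="ignore"):
        series = np.nanmean(cross, axis=1)
    return series / v_scale


def vorticity_stats(series: np.ndarray, times: Optional[np.ndarray] = None,
                    t_cont: Optional[float] = None):
    """Mean mu, SD sigma and vorticity V = |mu|/sigma of a transverse-
    velocity series, restricted to t <= t_cont when given.  Returns
    ``(mu, sd, V)``; V is +inf when the series is constant and non-zero."""
    s = np.asarray(series, dtype=float)
    if times is not None and t_cont is not None:
        s = s[np.asarray(times) <= t_cont]
    s = s[np.isfinite(s)]
    if len(s) == 0:
        raise AnalysisError("empty vorticity series")
    mu = float(np.mean(s))
    sd = float(np.std(s))
    if sd == 0.0:
        return mu, sd, (np.inf if mu != 0 else 0.0)
    return mu, sd, abs(mu) / sd


def mean_vorticity(per_run_V: Iterable[float]) -> float:
    """Multi-run mean vorticity; a parameter point is a vortex when this
    exceeds :data:`VORTEX_THRESHOLD`."""
    return float(np.mean(list(per_run_V)))


# ---------------------------------------------------------------- contraction

@dataclass
class ContractionFit:
    R_min: float
    dR: float
    t_cont: float
    dt_width: float
    contracted: bool
    residual_sd: float


def _tanh_model(t, R_min, dR, t_cont, dt_width):
    return R_min + dR * np.tanh((t - t_cont) / dt_width)


def fit_contraction(times: np.ndarray, R: np.ndarray,
                    t_max: Optional[float] = None) -> ContractionFit:
    """Least-squares fit of R(t) = R_min + dR * tanh[(t - t_cont)/dt].

    Initial guesses: R_min = min R, dR = (max - min)/2, t_cont = time of
    steepest descent, dt = span/10.  When no contraction is resolved
    (|dR| below twice the residual noise, t_cont outside the span, or a
    failed fit) ``t_cont`` is assigned ``t_max`` (default: the last time)
    and ``contracted`` is False.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(R, dtype=float)
    if len(t) < 8:
        raise AnalysisError("need at least 8 points for the contraction fit")
    if t_max is None:
        t_max = float(t[-1])
    span = float(t[-1] - t[0])
    dr_dt = np.gradient(r, t)
    p0 = [float(r.min()), float((r.max() - r.min()) / 2.0),
          float(t[np.argmin(dr_dt)]), span / 10.0]
    try:
        popt, _ = optimize.curve_fit(_tanh_model, t, r, p0=p0, maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning):
        sd = float(np.std(r))
        return ContractionFit(float(r.min()), 0.0, t_max, span / 10.0, False, sd)
    R_min, dR, t_cont, dt_width = (float(v) for v in popt)
    resid = r - _tanh_model(t, *popt)
    residual_sd = float(np.std(resid))
    ok = abs(dR) >= 2.0 * residual_sd and t[0] <= t_cont <= t[-1]
    if not ok:
        return ContractionFit(R_min, dR, t_max, abs(dt_width), False, residual_sd)
    return ContractionFit(R_min, dR, t_cont, abs(dt_width), True, residual_sd)


# ---------------------------------------------------------------- MSAD

def unwrap_angles(com_xy: np.ndarray, centers: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-filament azimuthal angles about the system centre, unwrapped
    continuously in time (frame-to-frame increments taken in (-pi, pi])."""
    com = np.asarray(com_xy, dtype=float)
    if centers is None:
        rel = com
    else:
        rel = com - np.asarray(centers, dtype=float)[:, None, :]
    theta = np.arctan2(rel[..., 1], rel[..., 0])
    return np.unwrap(theta, axis=0)


def msad(times: np.ndarray, com_xy: np.ndarray,
         centers: Optional[np.ndarray] = None,
         t_cont: Optional[float] = None):
    """Mean-squared angular displacement <(dtheta)^2>(dt).

    Angles are the unwrapped azimuths of filament centres of mass about the
    system centre; the average runs over all filaments and all waiting
    times up to ``t_cont``.  Returns ``(lags, values)`` for every positive
    multiple of the frame spacing.
    """
    t = np.asarray(times, dtype=float)
    if len(t) < 2:
        raise AnalysisError("need at least 2 frames for MSAD")
    theta = unwrap_angles(com_xy, centers)
    if t_cont is not None:
        keep = t <= t_cont
        t, theta = t[keep], theta[keep]
        if len(t) < 2:
            raise AnalysisError("no frames before t_cont")
    F = len(t)
    lags = np.empty(F - 1)
    vals = np.empty(F - 1)
    for k in range(1, F):
        d = theta[k:] - theta[:-k]
        lags[k - 1] = np.mean(t[k:] - t[:-k])
        vals[k - 1] = float(np.mean(d * d))
    return lags, vals


def msad_slope(lags: np.ndarray, values: np.ndarray,
               fit_range: Optional[tuple] = None) -> float:
    """Log-log slope of an MSAD curve (1 = diffusive, 2 = ballistic).

    By default fits the first half of the lag range (long lags are
    poorly averaged); zero values are excluded.
    """
    lags = np.asarray(lags, dtype=float)
    values = np.asarray(values, dtype=float)
    if fit_range is None:
        fit_range = (lags[0], lags[len(lags) // 2])
    keep = (lags >= fit_range[0]) & (lags <= fit_range[1]) & (values > 0)
    if np.sum(keep) < 2:
        raise AnalysisError("not enough points in MSAD fit range")
    coef = np.polyfit(np.log(lags[keep]), np.log(values[keep]), 1)
    return float(coef[0])


# ---------------------------------------------------------------- motors

def motor_statistics(state: SystemState):
    """Motors per filament ``n_mot/N`` and [+]-end fraction
    ``n_mot[+]/n_mot`` (None when there are no motors)."""
    from .motors import count_plus_end_motors
    N, M, _ = state.positions.shape
    n = state.n_mot
    per_fil = n / N
    if n == 0:
        return per_fil, None
    return per_fil, count_plus_end_motors(state.motors, M) / n


# ---------------------------------------------------------------- tests

def _a2_statistic(z: np.ndarray) -> np.ndarray:
    """Anderson-Darling A^2 from sorted CDF values (last axis)."""
    z = np.clip(z, 1e-12, 1.0 - 1e-12)
    n = z.shape[-1]
    i = np.arange(1, n + 1)
    return -n - np.mean((2 * i - 1) * (np.log(z) + np.log(1.0 - z[..., ::-1])), axis=-1) * 1.0


def anderson_darling(x: np.ndarray, dist: str) -> float:
    """A^2 against an exponential (estimated mean) or normal (estimated
    mean and variance, ddof=1) distribution."""
    x = np.sort(np.asarray(x, dtype=float))
    if dist == "exponential":
        z = 1.0 - np.exp(-x / x.mean())
    elif dist == "normal":
        z = stats.norm.cdf(x, loc=x.mean(), scale=x.std(ddof=1))
    else:
        raise ValueError(f"unknown distribution {dist!r}")
    return float(_a2_statistic(z))


def _bootstrap_p(x: np.ndarray, dist: str, a2_obs: float, n_boot: int,
                 rng: np.random.Generator) -> float:
    """Parametric-bootstrap p-value: A^2 is recomputed with re-estimated
    parameters on each resample, as for the observed data."""
    n = len(x)
    if dist == "exponential":
        sample = rng.exponential(x.mean(), size=(n_boot, n))
        sample.sort(axis=1)
        z = 1.0 - np.exp(-sample / sample.mean(axis=1, keepdims=True))
    else:
        sample = rng.normal(x.mean(), x.std(ddof=1), size=(n_boot, n))
        sample.sort(axis=1)
        mu = sample.mean(axis=1, keepdims=True)
        sd = sample.std(axis=1, ddof=1, keepdims=True)
        z = stats.norm.cdf(sample, loc=mu, scale=sd)
    a2 = _a2_statistic(z)
    return float(np.mean(a2 >= a2_obs))


def lifetime_tests(times: np.ndarray, n_boot: int = 10_000,
                   seed: int = 0) -> dict:
    """Goodness-of-fit of a lifetime sample to exponential vs normal.

    Returns A^2 statistics for (i) an exponential distribution with
    estimated mean and (ii) a normal distribution with estimated mean and
    variance, with p-values from a seeded parametric bootstrap.  A large
    exponential p alongside a small normal p indicates a constant-rate
    (Poisson) process rather than a fixed-time one.
    """
    x = np.asarray(times, dtype=float)
    if len(x) < 5:
        raise AnalysisError(f"need at least 5 values, got {len(x)}")
    rng = np.random.default_rng(seed)
    out = {"n": len(x), "mean": float(x.mean())}
    for dist, tag in (("exponential", "exp"), ("normal", "norm")):
        a2 = anderson_darling(x, dist)
        out[f"A2_{tag}"] = a2
        out[f"p_{tag}"] = _bootstrap_p(x, dist, a2, n_boot, rng)
    return out


def binomial_direction_test(n_one_way: int, n_other_way: int) -> float:
    """Exact two-sided binomial p-value for rotation-direction counts under
    equal probabilities for both directions."""
    n = n_one_way + n_other_way
    return float(stats.binomtest(n_one_way, n, 0.5).pvalue)


# ---------------------------------------------------------------- switching

def switching_times(times: np.ndarray, series: np.ndarray, window: int = 5):
    """Intervals between sign changes of a boxcar-smoothed series.

    Returns ``(intervals, mean, se)``; empty intervals (and nan summary)
    when the smoothed series never changes sign.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(series, dtype=float)
    if len(s) <= window:
        raise AnalysisError("series shorter than the smoothing window")
    if window > 1:
        kernel = np.ones(window) / window
        s = np.convolve(s, kernel, mode="valid")
        t = t[window - 1:] - (t[window - 1] - t[0]) / 2.0
    sign = np.sign(s)
    nz = sign != 0
    sign_ff = sign.copy()
    last = 0.0
    for k in range(len(sign_ff)):      # carry the last non-zero sign forward
        if sign_ff[k] == 0:
            sign_ff[k] = last
        else:
            last = sign_ff[k]
    change = np.nonzero(np.diff(sign_ff) != 0)[0]
    change = change[sign_ff[change] != 0]
    t_change = t[change + 1]
    intervals = np.diff(t_change)
    if len(intervals) == 0:
        return intervals, np.nan, np.nan
    mean = float(np.mean(intervals))
    se = float(np.std(intervals, ddof=1) / np.sqrt(len(intervals))) if len(intervals) > 1 else np.nan
    return intervals, mean, se
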