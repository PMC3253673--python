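"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from scipy.integrate import quad

# ---- independent quadrature oracle for the angular mode amplitudes ----
# The ideal polarity fields are restated here (not imported from the
# package) so the oracle stays independent of the code under test.

IDEAL_FIELD_DEFS = {
    "aster": ([(-np.pi, np.pi)],
              lambda t: (-np.cos(t), -np.sin(t))),
    "semi-aster": ([(-0.75 * np.pi, 0.75 * np.pi)],
                   lambda t: (-np.cos(t / 3.0), -np.sin(t / 3.0))),
    "spindle": ([(-0.25 * np.pi, 0.25 * np.pi), (0.75 * np.pi, 1.25 * np.pi)],
                lambda t: (-np.cos(t), np.sin(t))),
    "nematic": ([], None),
}


def quadrature_mode_amplitudes(state_name: str, m_max: int = 3) -> np.ndarray:
    """Q_0..Q_3 of an ideal field by direct numerical quadrature of the
    Fourier coefficient integrals a_m = int p cos(m t) dt etc."""
    intervals, field = IDEAL_FIELD_DEFS[state_name]
    Q = np.zeros(m_max + 1)
    for m in range(m_max + 1):
        a = np.zeros(2)
        b = np.zeros(2)
        for lo, hi in intervals:
            for c in range(2):
                a[c] += quad(lambda t: field(t)[c] * np.cos(m * t), lo, hi,
                             limit=200)[0]
                if m > 0:
                    b[c] += quad(lambda t: field(t)[c] * np.sin(m * t), lo, hi,
                                 limit=200)[0]
        Q[m] = (a @ a + b @ b) / (2.0 * np.pi ** 2)
    return Q


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_confined_state():
    """A few short filaments inside a small elastic wall, for force and
    energy checks that need every interaction active."""
    import motorgel as mg
    from motorgel.state import SystemState, make_wall

    params = mg.ModelParams(N=5, M=4, R0=6.0, n_wall=16, Z=5.0,
                            k_A=1.0, k_D=1.0, k_M=1.0, P=0.1, seed=3)
    gen = np.random.default_rng(12)
    positions = np.empty((5, 4, 3))
    for i in range(5):
        start = gen.uniform(-2.0, 2.0, size=3)
        start[2] = gen.uniform(1.5, 3.5)
        direction = gen.normal(size=3)
        direction /= np.linalg.norm(direction)
        positions[i] = start + np.outer(np.arange(4) * 1.0, direction)
        positions[i, :, 2] = np.clip(positions[i, :, 2], 0.8, params.Z - 0.8)
    motors = np.array([[0, 1, 1, 2], [2, 0, 3, 3]], dtype=np.int64)
    state = SystemState(positions, motors, make_wall(params.R0, params.n_wall))
    return params, state
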