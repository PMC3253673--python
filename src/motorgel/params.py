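"""Model parameters, unit normalisation and validation.

All quantities are expressed in reduced units: length in the bond length
``b``, energy in ``k_BT``, drag in the parallel monomer friction ``gamma``.
Time is then measured in ``gamma * b**2 / k_BT``; the natural filament time
scale is ``tau_b = L*b*gamma / (4*k_BT)``, the time for a free filament to
diffuse roughly one monomer spacing.  Pressure is reported relative to
``P0 = eps / b**3`` built from the excluded-volume energy ``eps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

__all__ = ["ModelParams", "ConfigurationError", "make_params", "physical_units_report"]

#: WCA cutoff factor, 2**(1/6)
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


class ConfigurationError(ValueError):
    """Raised for a missing, unknown or invalid configuration key."""


@dataclass(frozen=True)
class ModelParams:
    """All physical and numerical constants of one run (reduced units).

    Parameters
    ----------
    N, M : int
        Number of filaments and monomers per filament.
    b : float
        Bond length; the simulation length unit.
    sigma, eps : float
        Excluded-volume (WCA) diameter and energy.
    k_bond, kappa : float
        Bond spring constant [k_BT/b^2] and bending rigidity [b*k_BT].
    k_motor : float
        Motor spring constant [k_BT/b^2]; motors have zero rest length.
    attach_range : float
        Capture radius for motor attachment; defaults to the WCA cutoff.
    k_A, k_D, k_M, k_E : float
        Motor attachment, detachment, stepping and end-detachment rates
        [1/time].  ``k_E`` defaults to ``k_D``.
    gamma : float
        Parallel monomer friction; perpendicular drag is ``2*gamma``.
    kBT : float
        Thermal energy (1 in reduced units).
    P : float
        External pressure on the elastic side wall [k_BT/b^3].
    Z : float
        Gap between the flat confining plates.
    R0 : float
        Initial side-wall radius.
    n_wall : int
        Number of wall nodes.
    c_stretch, c_bend : float
        Wall elastic coefficients: stretch energy ``c_stretch*kBT*Z*dl^2/l0^3``
        per adjacent node pair and bend energy ``c_bend*kBT*l0*Z*dkappa^2``
        per node triplet.
    delta_w : float
        Wall Monte Carlo trial step half-width.
    dt : float
        Brownian dynamics time step.
    kinetics_interval, wall_interval : int
        BD steps between motor-kinetics sweeps and wall MC sweeps.
    t_end : float
        Run length.
    seed : int
        Master RNG seed.
    volume_mode : str
        ``"pressure"`` (elastic wall + PV Monte Carlo) or ``"fixed"``
        (rigid circular wall following an imposed radius schedule).
    """

    N: int = 175
    M: int = 30
    b: float = 1.0
    sigma: Optional[float] = None
    eps: float = 5.0
    k_bond: float = 100.0
    kappa: float = 200.0
    k_motor: float = 1.0
    attach_range: Optional[float] = None
    k_A: float = 0.0
    k_D: float = 0.0
    k_M: float = 0.0
    k_E: Optional[float] = None
    gamma: float = 1.0
    kBT: float = 1.0
    P: float = 0.0
    Z: float = 5.0
    R0: float = 40.0
    n_wall: int = 80
    c_stretch: float = 0.5
    c_bend: float = 1.0e3
    delta_w: float = 0.1
    dt: float = 5.0e-4
    kinetics_interval: int = 10
    wall_interval: int = 10
    t_end: float = 10.0
    seed: int = 0
    volume_mode: str = "pressure"

    def __post_init__(self) -> None:
        if self.sigma is None:
            object.__setattr__(self, "sigma", self.b)
        if self.attach_range is None:
            object.__setattr__(self, "attach_range", WCA_CUTOFF * self.sigma)
        if self.k_E is None:
            object.__setattr__(self, "k_E", self.k_D)
        self._validate()

    def _validate(self) -> None:
        if self.M < 2:
            raise ConfigurationError(f"M must be >= 2, got {self.M}")
        if self.N < 1:
            raise ConfigurationError(f"N must be >= 1, got {self.N}")
        if self.n_wall < 3:
            raise ConfigurationError(f"n_wall must be >= 3, got {self.n_wall}")
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")
        if self.t_end < 0:
            raise ConfigurationError(f"t_end must be >= 0, got {self.t_end}")
        for key in ("b", "sigma", "Z", "R0", "gamma", "kBT"):
            if getattr(self, key) <= 0:
                raise ConfigurationError(f"{key} must be > 0, got {getattr(self, key)}")
        for key in (
            "eps", "k_bond", "kappa", "k_motor", "attach_range",
            "k_A", "k_D", "k_M", "k_E", "P", "c_stretch", "c_bend", "delta_w",
        ):
            if getattr(self, key) < 0:
                raise ConfigurationError(f"{key} must be >= 0, got {getattr(self, key)}")
        for key in ("kinetics_interval", "wall_interval"):
            if getattr(self, key) < 1:
                raise ConfigurationError(f"{key} must be >= 1, got {getattr(self, key)}")
        if self.volume_mode not in ("pressure", "fixed"):
            raise ConfigurationError(
                f"volume_mode must be 'pressure' or 'fixed', got {self.volume_mode!r}"
            )

    # ---- derived quantities (never stored) ----

    @property
    def L(self) -> float:
        """Filament contour length M*b."""
        return self.M * self.b

    @property
    def tau_b(self) -> float:
        """Monomer-diffusion time L*b*gamma/(4 k_BT)."""
        return self.L * self.b * self.gamma / (4.0 * self.kBT)

    @property
    def P0(self) -> float:
        """Pressure unit eps/b^3."""
        return self.eps / self.b ** 3

    @property
    def l_p(self) -> float:
        """Persistence length kappa/k_BT (kappa carries a factor of b)."""
        return self.kappa / self.kBT

    @property
    def wca_cutoff(self) -> float:
        return WCA_CUTOFF * self.sigma

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


_FIELD_NAMES = {f.name for f in fields(ModelParams)}


def make_params(config: dict) -> ModelParams:
    """Build a validated :class:`ModelParams` from a flat key-value mapping.

    Unknown keys are rejected; values must be numeric (or the ``volume_mode``
    string).  Raises :class:`ConfigurationError` naming the offending key.
    """
    unknown = set(config) - _FIELD_NAMES
    if unknown:
        raise ConfigurationError(f"unknown parameter key(s): {sorted(unknown)}")
    clean = {}
    for key, value in config.items():
        if key == "volume_mode":
            clean[key] = str(value)
            continue
        if isinstance(value, bool) or not isinstance(value, (int, float, str)):
            raise ConfigurationError(f"parameter {key!r} has non-numeric value {value!r}")
        try:
            num = float(value)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"parameter {key!r} is not numeric: {value!r}") from exc
        if key in ("N", "M", "n_wall", "kinetics_interval", "wall_interval", "seed"):
            if num != int(num):
                raise ConfigurationError(f"parameter {key!r} must be an integer, got {value!r}")
            clean[key] = int(num)
        else:
            clean[key] = num
    return ModelParams(**clean)


def physical_units_report(
    params: ModelParams, b_nm: float = 10.0, kBT_pN_nm: float = 4.114
) -> dict:
    """Map reduced units to physical units for a chosen monomer size.

    With ``b_nm`` the bond length in nanometres (10 nm sits between actin,
    ~7 nm, and microtubules, ~25 nm) and ``kBT_pN_nm`` the thermal energy in
    pN*nm (4.114 at 300 K), returns the physical length, force and filament
    scale of the model.
    """
    return {
        "b_nm": b_nm,
        "kBT_pN_nm": kBT_pN_nm,
        "force_unit_pN": kBT_pN_nm / b_nm,
        "filament_length_um": params.L / params.b * b_nm * 1e-3,
        "persistence_length_um": params.l_p * b_nm * 1e-3,
        "pressure_unit_P0_kBT_per_b3": params.P0,
        "tau_b_reduced": params.tau_b,
    }
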