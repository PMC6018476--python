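"""Physical <-> lattice unit conversion.

A :class:`UnitSystem` is the triple (dx, dt, rho_ref).  Lattice quantities
are non-dimensionalized so that the voxel spacing, time step and reference
density are all unity; every physical quantity converts by the appropriate
power of dx, dt and rho_ref.

The kinematic viscosity of the BGK model and the lattice sound speed are

    nu  = (1/3) (tau - 1/2) dx^2 / dt,
    c_s = dx / (sqrt(3) dt),

which give the (dimensionless) relaxation parameter tau from a physical
viscosity and the compressibility scale of the scheme.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "UnitSystem",
    "speed_of_sound",
    "relaxation_from_viscosity",
    "viscosity_from_relaxation",
    "convert_units",
    "StabilityWarning",
]


class StabilityWarning(UserWarning):
    """Relaxation parameter outside the configured stability window."""


#: scale exponents (power of dx, power of dt, power of rho_ref) per quantity
_KIND_EXPONENTS = {
    "length": (1, 0, 0),
    "time": (0, 1, 0),
    "velocity": (1, -1, 0),
    "acceleration": (1, -2, 0),
    "shear_rate": (0, -1, 0),
    "density": (0, 0, 1),
    "pressure": (2, -2, 1),
    "viscosity": (2, -1, 1),  # dynamic viscosity, Pa s
    "kinematic_viscosity": (2, -1, 0),
}


@dataclass(frozen=True)
class UnitSystem:
    """Lattice spacing dx [m], time step dt [s], reference density [kg/m^3]."""

    dx: float
    dt: float
    rho_ref: float = 1000.0

    def __post_init__(self):
        if self.dx <= 0 or self.dt <= 0 or self.rho_ref <= 0:
            raise ValueError("dx, dt and rho_ref must all be positive")

    def to_lattice(self, value, kind: str):
        return convert_units(value, kind, "to_lattice", self)

    def to_physical(self, value, kind: str):
        return convert_units(value, kind, "to_physical", self)


def convert_units(value, quantity_kind: str, direction: str, unit: UnitSystem):
    """Scale ``value`` between physical (SI) and lattice units.

    ``quantity_kind`` selects the powers of dx, dt and rho_ref; the two
    directions are exact inverses.
    """
    try:
        px, pt, pr = _KIND_EXPONENTS[quantity_kind]
    except KeyError:
        raise ValueError(
            f"unknown quantity kind {quantity_kind!r}; expected one of "
            f"{sorted(_KIND_EXPONENTS)}"
        ) from None
    scale = unit.dx**px * unit.dt**pt * unit.rho_ref**pr
    if direction == "to_lattice":
        return value / scale
    if direction == "to_physical":
        return value * scale
    raise ValueError("direction must be 'to_lattice' or 'to_physical'")


def speed_of_sound(unit: UnitSystem) -> float:
    """Physical lattice sound speed c_s = dx / (sqrt(3) dt) in m/s."""
    return unit.dx / (math.sqrt(3.0) * unit.dt)


def relaxation_from_viscosity(
    nu: float,
    unit: UnitSystem,
    stability_window: tuple[float, float] = (0.5 + 1e-6, 10.0),
) -> float:
    """Relaxation parameter tau for a physical kinematic viscosity [m^2/s].

    Inverts nu = (1/3)(tau - 1/2) dx^2/dt.  Emits a
    :class:`StabilityWarning` when tau falls outside ``stability_window``
    (tau <= 0.5 is linearly unstable; very large tau degrades accuracy).
    """
    if nu <= 0:
        raise ValueError("kinematic viscosity must be positive")
    nu_lat = convert_units(nu, "kinematic_viscosity", "to_lattice", unit)
    tau = 0.5 + 3.0 * nu_lat
    lo, hi = stability_window
    if not (lo <= tau <= hi):
        warnings.warn(
            f"tau = {tau:.6g} outside stability window [{lo}, {hi}]",
            StabilityWarning,
            stacklevel=2,
        )
    return tau


def viscosity_from_relaxation(tau: float, unit: UnitSystem) -> float:
    """Physical kinematic viscosity [m^2/s] for relaxation parameter tau."""
    nu_lat = (tau - 0.5) / 3.0
    return convert_units(nu_lat, "kinematic_viscosity", "to_physical", unit)
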