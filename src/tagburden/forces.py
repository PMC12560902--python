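"""Force/coefficient conversions and tag-impact deltas.

Dimensionless coefficients are referenced to the dynamic pressure
``q = 1/2 rho U^2`` and the maximum frontal area A:

    C_D = 2 F_D / (rho A U^2)
    C_L = 2 F_L / (rho A U^2)
    C_M = 2 M_P / (rho A L U^2)

with the fork length L as the moment reference length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, InvalidInputError
from .physics import FluidProperties, SharkGeometry


@dataclass(frozen=True)
class ForceBalance:
    """Net hydrodynamic forces and pitching moment on a body.

    Sign conventions: drag positive along the flow, lift positive upward,
    side force positive toward the tagged side, pitch moment about the
    body's centre of rotation.
    """

    drag_force: float = 0.0  # N
    lift_force: float = 0.0  # N
    side_force: float = 0.0  # N
    pitch_moment: float = 0.0  # N.m


@dataclass(frozen=True)
class CoefficientSet:
    """Dimensionless drag, lift and pitching-moment coefficients."""

    c_drag: float
    c_lift: float = 0.0
    c_moment: float = 0.0

    def __post_init__(self) -> None:
        if self.c_drag < 0:
            raise InvalidInputError(f"c_drag must be >= 0, got {self.c_drag}")


def _dynamic_pressure_area(
    fluid: FluidProperties, geometry: SharkGeometry, speed: float
) -> float:
    if geometry.frontal_area is None or geometry.frontal_area <= 0:
        raise ConfigurationError("geometry.frontal_area is required for conversions")
    return 0.5 * fluid.density * geometry.frontal_area * speed**2


def coefficient_to_force(
    c: float, fluid: FluidProperties, geometry: SharkGeometry, speed: float
) -> float:
    """Force (N) from a coefficient: F = 1/2 rho A U^2 c."""
    if speed < 0:
        raise InvalidInputError(f"speed must be >= 0, got {speed}")
    return _dynamic_pressure_area(fluid, geometry, speed) * c


def force_to_coefficient(
    f: float, fluid: FluidProperties, geometry: SharkGeometry, speed: float
) -> float:
    """Coefficient from a force: c = 2 F / (rho A U^2).  Requires U > 0."""
    if speed <= 0:
        raise InvalidInputError(
            f"speed must be > 0 to nondimensionalise a force, got {speed}"
        )
    return f / _dynamic_pressure_area(fluid, geometry, speed)


def moment_to_coefficient(
    m: float, fluid: FluidProperties, geometry: SharkGeometry, speed: float
) -> float:
    """Pitching-moment coefficient: C_M = 2 M_P / (rho A L U^2)."""
    if speed <= 0:
        raise InvalidInputError(
            f"speed must be > 0 to nondimensionalise a moment, got {speed}"
        )
    return m / (_dynamic_pressure_area(fluid, geometry, speed) * geometry.fork_length)


def percent_increase(base: float, tagged: float) -> float:
    """Relative change 100 (tagged - base) / base, in percent.

    May be negative: archival tags shed a fraction of a drag count at high
    speed in the packaged tables, and those deltas are retained verbatim.
    """
    if base <= 0:
        raise InvalidInputError(f"baseline must be > 0, got {base}")
    return 100.0 * (tagged - base) / base
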