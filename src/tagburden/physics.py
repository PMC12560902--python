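"""Physical constants, flow conditions, body geometry and Reynolds numbers.

All quantities are SI: lengths in m, speeds in m/s, masses in kg, density in
kg/m^3, dynamic viscosity in Pa.s.  The characteristic length of a shark is
its fork length (snout to fork of the caudal fin); the reference area for
force coefficients is the maximum frontal cross-sectional area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

from .errors import InvalidInputError

#: Seawater at 20 degC, the habitat temperature band of pelagic lamnids.
SEAWATER_DENSITY = 1025.0  # kg/m^3
SEAWATER_DYNAMIC_VISCOSITY = 0.00109  # Pa.s

#: Default frontal-area coefficient: A = C_A * L^2.  Chosen so a 2.95 m
#: adult has A ~= 0.12 m^2, a plausible slender-body frontal area.  A cancels
#: in every ratio metric (percent drag/energy increase), so this default only
#: affects absolute forces and energies.
DEFAULT_AREA_COEFFICIENT = 0.12 / 2.95**2

#: Length-mass anchor: a 1 m fork-length mako weighs about 17 kg; isometric
#: (cubic) scaling is the default exponent.
DEFAULT_MASS_ANCHOR_LENGTH = 1.0  # m
DEFAULT_MASS_ANCHOR_MASS = 17.0  # kg
DEFAULT_MASS_EXPONENT = 3.0


@dataclass(frozen=True)
class FluidProperties:
    """Density and dynamic viscosity of the working fluid."""

    density: float = SEAWATER_DENSITY
    dynamic_viscosity: float = SEAWATER_DYNAMIC_VISCOSITY

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise InvalidInputError(f"density must be > 0, got {self.density}")
        if self.dynamic_viscosity <= 0:
            raise InvalidInputError(
                f"dynamic_viscosity must be > 0, got {self.dynamic_viscosity}"
            )

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu / rho, in m^2/s."""
        return self.dynamic_viscosity / self.density


@dataclass(frozen=True)
class FlowCondition:
    """Free-stream velocity and turbulence intensity of the oncoming flow."""

    speed: float
    turbulence_intensity: float = 0.02

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise InvalidInputError(f"speed must be >= 0, got {self.speed}")
        if not 0 <= self.turbulence_intensity < 1:
            raise InvalidInputError(
                "turbulence_intensity must lie in [0, 1), got "
                f"{self.turbulence_intensity}"
            )


class TagKind(str, Enum):
    """Tag families distinguished by attachment style and flow exposure.

    ``archival_body`` is a pop-up archival (MiniPAT-class) tag pinned along
    the dorsal musculature, shielded within the body's cross-section;
    ``fin_mount`` is a position/temperature transmitter (SPOT-class) bolted
    to the dorsal fin, protruding into the free stream.
    """

    NONE = "none"
    ARCHIVAL_BODY = "archival_body"
    FIN_MOUNT = "fin_mount"


@dataclass(frozen=True)
class TagConfig:
    """A tag type, its attachment site and its mass in air.

    ``placement_site`` (1-4, anterior to posterior along the dorsal flank)
    is meaningful only for archival body tags; fin-mount tags have a single
    dorsal-fin position.
    """

    tag_kind: TagKind = TagKind.NONE
    placement_site: Optional[int] = None
    mass_in_air: float = 0.0

    def __post_init__(self) -> None:
        if self.mass_in_air < 0:
            raise InvalidInputError(
                f"mass_in_air must be >= 0, got {self.mass_in_air}"
            )
        if self.placement_site is not None:
            if self.tag_kind is not TagKind.ARCHIVAL_BODY:
                raise InvalidInputError(
                    "placement_site is defined only for archival body tags"
                )
            if self.placement_site not in (1, 2, 3, 4):
                raise InvalidInputError(
                    f"placement_site must be 1-4, got {self.placement_site}"
                )


@dataclass(frozen=True)
class SharkGeometry:
    """Fork length, frontal area and (optional) body mass of a shark.

    If ``frontal_area`` is omitted it defaults to ``C_A * L^2`` with the
    package's slender-body area coefficient.
    """

    fork_length: float
    frontal_area: Optional[float] = None
    mass: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fork_length <= 0:
            raise InvalidInputError(
                f"fork_length must be > 0, got {self.fork_length}"
            )
        if self.frontal_area is None:
            object.__setattr__(
                self,
                "frontal_area",
                DEFAULT_AREA_COEFFICIENT * self.fork_length**2,
            )
        elif self.frontal_area <= 0:
            raise InvalidInputError(
                f"frontal_area must be > 0, got {self.frontal_area}"
            )
        if self.mass is not None and self.mass <= 0:
            raise InvalidInputError(f"mass must be > 0, got {self.mass}")


def reynolds_number(
    fluid: FluidProperties, geometry: SharkGeometry, speed: float
) -> float:
    """Reynolds number Re = rho * U * L / mu.

    The ratio of inertial to viscous forces, with the fork length as the
    characteristic length.  Linear in both speed and fork length; zero at
    zero speed.
    """
    if speed < 0:
        raise InvalidInputError(f"speed must be >= 0, got {speed}")
    return fluid.density * speed * geometry.fork_length / fluid.dynamic_viscosity


def scale_geometry(geometry: SharkGeometry, target_fork_length: float) -> SharkGeometry:
    """Uniform isometric scaling of a shark geometry to a new fork length.

    Lengths scale by s = target/original, areas by s^2 and masses by s^3.
    """
    if target_fork_length <= 0:
        raise InvalidInputError(
            f"target_fork_length must be > 0, got {target_fork_length}"
        )
    s = target_fork_length / geometry.fork_length
    return replace(
        geometry,
        fork_length=target_fork_length,
        frontal_area=geometry.frontal_area * s**2,
        mass=None if geometry.mass is None else geometry.mass * s**3,
    )


@dataclass(frozen=True)
class MassModel:
    """Allometric length-mass model ``mass = anchor_mass * (L/anchor_L)^b``.

    Defaults to isometry (b = 3) anchored at 1 m / 17 kg.
    """

    anchor_length: float = DEFAULT_MASS_ANCHOR_LENGTH
    anchor_mass: float = DEFAULT_MASS_ANCHOR_MASS
    exponent: float = DEFAULT_MASS_EXPONENT

    def __post_init__(self) -> None:
        if self.anchor_length <= 0 or self.anchor_mass <= 0:
            raise InvalidInputError("mass-model anchors must be > 0")


def estimate_mass(fork_length: float, model: MassModel = MassModel()) -> float:
    """Body mass (kg) from fork length via the allometric model."""
    if fork_length <= 0:
        raise InvalidInputError(f"fork_length must be > 0, got {fork_length}")
    return model.anchor_mass * math.pow(fork_length / model.anchor_length, model.exponent)
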