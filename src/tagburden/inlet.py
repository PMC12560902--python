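"""Inlet turbulence quantities for external RANS case setup.

Rule-of-thumb initialisation of turbulent kinetic energy k, its dissipation
rate epsilon and the specific dissipation rate omega from the free-stream
velocity, turbulence intensity and a length scale of 7% of the body length:

    k       = 2/3 (U Ti)^2
    epsilon = C_mu^(3/4) k^(3/2) / (0.07 L),  C_mu = 0.09
    omega   = epsilon / k

The writer emits a solver-agnostic key-value block (or JSON) rather than
any solver-specific dictionary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .errors import InvalidInputError
from .physics import FlowCondition, SharkGeometry

C_MU = 0.09  # standard eddy-viscosity model constant


@dataclass(frozen=True)
class InletTurbulence:
    """k (m^2/s^2), epsilon (m^2/s^3) and omega (1/s) at the domain inlet."""

    tke: float
    dissipation: float
    specific_dissipation: float


def inlet_conditions(flow: FlowCondition, geometry: SharkGeometry) -> InletTurbulence:
    """Inlet k, epsilon, omega for a given flow and body length.

    Zero speed or zero turbulence intensity is rejected: an all-zero
    turbulence field is not a valid inlet state for a turbulence model.
    """
    if flow.speed <= 0:
        raise InvalidInputError("inlet conditions require speed > 0")
    if flow.turbulence_intensity <= 0:
        raise InvalidInputError("inlet conditions require turbulence_intensity > 0")
    k = (2.0 / 3.0) * (flow.speed * flow.turbulence_intensity) ** 2
    epsilon = C_MU**0.75 * k**1.5 / (0.07 * geometry.fork_length)
    return InletTurbulence(tke=k, dissipation=epsilon, specific_dissipation=epsilon / k)


def format_inlet_block(inlet: InletTurbulence) -> str:
    """Flat key-value text block with units in comments."""
    return (
        "# inlet turbulence quantities\n"
        f"k {inlet.tke:.6g}  # turbulent kinetic energy, m^2/s^2\n"
        f"epsilon {inlet.dissipation:.6g}  # dissipation rate, m^2/s^3\n"
        f"omega {inlet.specific_dissipation:.6g}  # specific dissipation rate, 1/s\n"
    )


def format_inlet_json(inlet: InletTurbulence) -> str:
    return json.dumps(
        {
            "k": inlet.tke,
            "epsilon": inlet.dissipation,
            "omega": inlet.specific_dissipation,
        },
        indent=2,
    )
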