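"""Burst-speed compensation under equal power, and weight-ratio rules.

If the power an untagged shark produces at its burst speed is the upper
bound of its capability, a tagged shark must slow down until its propulsive
power P = F_drag * v matches that bound.  Two readings of this compensation
are provided:

``fixed_force``
    Drag is held at its burst-speed value on both sides, so
    ``F_tag(v_b) * v' = F_untag(v_b) * v_b`` and the reduced speed is
    ``v' = v_b / (1 + delta)`` with delta the fractional drag increase at
    v_b; the percent reduction is ``100 delta / (1 + delta)``.  This is
    the default because it reproduces the arithmetic behind published
    speed-reduction figures for fin-mounted tags.

``cd_interpolated``
    Drag is re-evaluated at the reduced speed through the coefficient
    interpolant, i.e. the cubic power law
    ``C_D,tag(v') v'^3 = C_D,untag(v_b) v_b^3`` is solved by bisection.
    For a speed-independent coefficient ratio (1 + delta) this has the
    closed form ``v' = v_b (1 + delta)^(-1/3)``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dragtable import DragCoefficientTable, lookup_cd
from .errors import InvalidInputError, RangeError
from .physics import FluidProperties, SharkGeometry

#: Speed tolerance (m/s) for the bisection solve.
BISECTION_TOL = 1e-6
#: Lower bracket edge: the slowest tabulated swim speed.
BRACKET_FLOOR = 0.5


@dataclass(frozen=True)
class SpeedReduction:
    """Equal-power compensated burst speed and its percent reduction."""

    reduced_speed: float  # m/s
    reduction_percent: float
    variant: str


def burst_speed_reduction(
    untagged_burst_speed: float,
    untagged: DragCoefficientTable,
    tagged: DragCoefficientTable,
    fluid: FluidProperties,
    geometry: SharkGeometry,
    variant: str = "fixed_force",
) -> SpeedReduction:
    """Reduced burst speed of a tagged shark at equal propulsive power."""
    v_b = untagged_burst_speed
    size = geometry.fork_length
    lo, hi = untagged.speed_range
    if not lo <= v_b <= hi:
        raise RangeError(f"burst speed {v_b} m/s outside table range [{lo}, {hi}]")

    cd_u = lookup_cd(untagged, size, v_b, clamp=False)
    cd_t = lookup_cd(tagged, size, v_b, clamp=False)

    if variant == "fixed_force":
        delta = cd_t / cd_u - 1.0
        reduced = v_b / (1.0 + delta)
    elif variant == "cd_interpolated":
        target = cd_u * v_b**3

        def power_excess(v: float) -> float:
            return lookup_cd(tagged, size, v, clamp=True) * v**3 - target

        a, b = BRACKET_FLOOR, v_b
        fa, fb = power_excess(a), power_excess(b)
        if fb <= 0:  # tagged drag does not exceed untagged at v_b
            reduced = v_b
        elif fa > 0:
            raise RangeError(
                "equal-power speed lies below the table's speed range "
                f"[{a}, {b}] m/s"
            )
        else:
            while b - a > BISECTION_TOL:
                mid = 0.5 * (a + b)
                if power_excess(mid) > 0:
                    b = mid
                else:
                    a = mid
            reduced = 0.5 * (a + b)
    else:
        raise InvalidInputError(
            f"variant must be 'fixed_force' or 'cd_interpolated', got {variant!r}"
        )

    return SpeedReduction(
        reduced_speed=reduced,
        reduction_percent=100.0 * (1.0 - reduced / v_b),
        variant=variant,
    )


def weight_ratio(
    tag_mass_in_air: float, body_mass: float, threshold: float = 3.0
) -> tuple[float, bool]:
    """Tag-to-body weight ratio (percent) against a rule-of-thumb threshold.

    ``threshold`` is in percent (2 for the teleost rule, 3 for the avian
    rule); the boundary counts as within the rule.  Uses mass in air, as
    weight-rule assessments conventionally (if imperfectly) do.
    """
    if body_mass <= 0:
        raise InvalidInputError(f"body_mass must be > 0, got {body_mass}")
    if tag_mass_in_air < 0:
        raise InvalidInputError(f"tag_mass_in_air must be >= 0, got {tag_mass_in_air}")
    ratio = 100.0 * tag_mass_in_air / body_mass
    return ratio, ratio <= threshold
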