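"""Synthetic drag-coefficient sweeps emulating steady-RANS output.

A CFD drag sweep over the Reynolds-number range of a swimming shark is
emulated by a flat-plate turbulent friction line with a form factor,
referenced to frontal area, plus a speed-independent pressure term and an
additive tag drag area:

    C_D(Re) = pressure_cd
              + form_factor * 0.074 Re^(-1/5) * (S_w / A)
              + tag_drag_area_ratio

``0.074 Re^(-1/5)`` is the Prandtl power-law skin-friction coefficient of a
flat plate (wetted-area referenced); multiplying by the wetted-to-frontal
area ratio S_w/A re-references it to the frontal area used by the drag
tables, and the form factor accounts for three-dimensional thickness
effects.  The tag term models an appendage whose drag area C_D,tag * A_tag
is constant relative to the host's frontal area — the statistical structure
observed in simulated tagged/untagged sweeps (a near-constant additive
coefficient offset).  Optional Gaussian cell noise (truncated at zero)
models solver convergence scatter.

Fitting: pressure_cd and tag_drag_area_ratio are both speed-independent,
so a single table identifies only their sum; ``fit_surrogate`` therefore
estimates a combined friction scale (form_factor * S_w/A) and a constant
offset, and ``fit_surrogate_pair`` recovers the tag drag-area ratio as the
difference of offsets between a tagged and an untagged table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .dragtable import DragCoefficientTable
from .errors import FitError, InvalidInputError
from .physics import FluidProperties, SharkGeometry, reynolds_number, scale_geometry

#: Prandtl power-law flat-plate friction coefficient prefactor.
FRICTION_PREFACTOR = 0.074
FRICTION_EXPONENT = -0.2

#: Noise default comparable to a three-decimal printing precision.
DEFAULT_NOISE_SD = 0.002


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the friction-line drag surrogate."""

    form_factor: float = 1.15
    wetted_to_frontal_ratio: float = 25.0
    pressure_cd: float = 0.0
    tag_drag_area_ratio: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.form_factor < 1:
            raise InvalidInputError("form_factor must be >= 1")
        if self.wetted_to_frontal_ratio <= 0:
            raise InvalidInputError("wetted_to_frontal_ratio must be > 0")
        if self.pressure_cd < 0 or self.tag_drag_area_ratio < 0:
            raise InvalidInputError("pressure_cd and tag_drag_area_ratio must be >= 0")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")

    @property
    def friction_scale(self) -> float:
        """Combined scale form_factor * S_w/A multiplying the friction line."""
        return self.form_factor * self.wetted_to_frontal_ratio

    def with_tag(self, tag_drag_area_ratio: float) -> "SurrogateParams":
        return replace(self, tag_drag_area_ratio=tag_drag_area_ratio)


def surrogate_cd(params: SurrogateParams, re) -> np.ndarray | float:
    """Noiseless surrogate drag coefficient at Reynolds number(s) ``re``.

    Strictly decreasing in Re whenever the friction term is active.
    """
    re = np.asarray(re, dtype=float)
    if np.any(re <= 0):
        raise InvalidInputError("Reynolds number must be > 0")
    cd = (
        params.pressure_cd
        + params.friction_scale * FRICTION_PREFACTOR * re**FRICTION_EXPONENT
        + params.tag_drag_area_ratio
    )
    return cd if cd.ndim else float(cd)


def generate_table(
    params: SurrogateParams,
    speeds: Sequence[float],
    sizes: Sequence[float],
    fluid: FluidProperties,
    geometry: SharkGeometry,
    config: str = "synthetic",
) -> DragCoefficientTable:
    """Synthetic drag table over a (speed, size) grid.

    Cells are surrogate values at each cell's Reynolds number; when
    ``params.noise_sd > 0``, independent Gaussian noise is added on the
    coefficient scale and truncated at zero.  Identical params (including
    seed) give bit-identical tables.
    """
    speeds = np.asarray(speeds, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    values = np.empty((speeds.size, sizes.size))
    for j, size in enumerate(sizes):
        geom = scale_geometry(geometry, size)
        re = np.array([reynolds_number(fluid, geom, u) for u in speeds])
        values[:, j] = surrogate_cd(params, re)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        values = values + rng.normal(0.0, params.noise_sd, size=values.shape)
        values = np.clip(values, np.finfo(float).tiny, None)
    return DragCoefficientTable(speeds=speeds, sizes=sizes, values=values, config=config)


@dataclass(frozen=True)
class SurrogateFit:
    """Least-squares fit of a drag table to the surrogate basis."""

    friction_scale: float
    offset: float  # pressure_cd + tag_drag_area_ratio, not separable
    residuals: np.ndarray
    rms_residual: float

    @property
    def max_abs_residual(self) -> float:
        return float(np.abs(self.residuals).max())

    def to_params(self, noise_sd: float = 0.0, seed: int = 0) -> SurrogateParams:
        """Params reproducing the fit, with the offset folded into pressure_cd."""
        return SurrogateParams(
            form_factor=1.0,
            wetted_to_frontal_ratio=self.friction_scale,
            pressure_cd=max(self.offset, 0.0),
            noise_sd=noise_sd,
            seed=seed,
        )


def fit_surrogate(
    table: DragCoefficientTable,
    fluid: FluidProperties,
    geometry: SharkGeometry,
    size: Optional[float] = None,
) -> SurrogateFit:
    """Fit (friction scale, constant offset) to one size column of a table.

    Ordinary least squares against the ``Re^(-1/5)`` basis.  Requires at
    least four speed knots; a constant column (no Reynolds dependence) is
    rejected as degenerate.
    """
    if size is None:
        size = float(table.sizes[0]) if table.sizes.size == 1 else geometry.fork_length
    if table.speeds.size < 4:
        raise FitError("surrogate fit requires at least 4 speed knots")
    cd = table.column(size)
    if np.allclose(cd, cd[0]):
        raise FitError("constant C_D column: friction scale unidentifiable")
    geom = scale_geometry(geometry, size)
    re = np.array([reynolds_number(fluid, geom, u) for u in table.speeds])
    basis = np.column_stack(
        [FRICTION_PREFACTOR * re**FRICTION_EXPONENT, np.ones_like(re)]
    )
    coef, *_ = np.linalg.lstsq(basis, cd, rcond=None)
    resid = cd - basis @ coef
    return SurrogateFit(
        friction_scale=float(coef[0]),
        offset=float(coef[1]),
        residuals=resid,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def fit_surrogate_pair(
    untagged: DragCoefficientTable,
    tagged: DragCoefficientTable,
    fluid: FluidProperties,
    geometry: SharkGeometry,
    size: Optional[float] = None,
) -> tuple[SurrogateFit, SurrogateFit, float]:
    """Fit both tables; the offset difference estimates tag_drag_area_ratio."""
    fu = fit_surrogate(untagged, fluid, geometry, size)
    ft = fit_surrogate(tagged, fluid, geometry, size)
    return fu, ft, ft.offset - fu.offset
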