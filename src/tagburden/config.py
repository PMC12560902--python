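"""Shared run configuration (YAML or JSON) and its validation.

Schema::

    fluid:      {density, dynamic_viscosity}
    geometry:   {fork_length, frontal_area | area_coefficient}
    mass_model: {anchor_length, anchor_mass, exponent}
    scenarios:  {burst_speeds, burst_fractions, glide_fraction, cruise_speed}
    tag_configs: [archival_body, fin_mount]
    drag_table: optional path to a drag-table CSV (packaged tables if absent)

Units are fixed by this contract (m, m/s, kg, SI fluid properties); no unit
inference is performed on input files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .energetics import (
    DEFAULT_BURST_FRACTIONS,
    DEFAULT_BURST_SPEEDS,
    DEFAULT_CRUISE_SPEED,
    DEFAULT_GLIDE_FRACTION,
)
from .errors import ConfigurationError
from .physics import FluidProperties, MassModel, SharkGeometry, TagKind

_VALID_TAG_CONFIGS = {k.value for k in TagKind} - {TagKind.NONE.value}


def default_config() -> dict[str, Any]:
    return {
        "fluid": {"density": 1025.0, "dynamic_viscosity": 0.00109},
        "geometry": {"fork_length": 2.95},
        "mass_model": {"anchor_length": 1.0, "anchor_mass": 17.0, "exponent": 3.0},
        "scenarios": {
            "burst_speeds": list(DEFAULT_BURST_SPEEDS),
            "burst_fractions": list(DEFAULT_BURST_FRACTIONS),
            "glide_fraction": DEFAULT_GLIDE_FRACTION,
            "cruise_speed": DEFAULT_CRUISE_SPEED,
        },
        "tag_configs": ["archival_body", "fin_mount"],
        "drag_table": None,
    }


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: Optional[Union[str, Path]] = None) -> dict[str, Any]:
    """Load and validate a config file, merged over the defaults."""
    config = default_config()
    if path is not None:
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix == ".json":
            user = json.loads(text)
        else:
            user = yaml.safe_load(text)
        if not isinstance(user, Mapping):
            raise ConfigurationError(f"config root must be a mapping: {path}")
        config = _merge(config, user)
    validate_config(config)
    return config


def validate_config(config: Mapping[str, Any]) -> None:
    """Schema checks; raises ConfigurationError naming the offending field."""
    known = set(default_config())
    unknown = set(config) - known
    if unknown:
        raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
    for cfg in config.get("tag_configs", []):
        if cfg not in _VALID_TAG_CONFIGS:
            raise ConfigurationError(
                f"tag_configs: unknown label {cfg!r}; expected one of "
                f"{sorted(_VALID_TAG_CONFIGS)}"
            )
    sc = config.get("scenarios", {})
    for field in ("burst_speeds", "burst_fractions"):
        if not sc.get(field):
            raise ConfigurationError(f"scenarios.{field}: must be a non-empty list")
    if not 0 <= sc.get("glide_fraction", 0) < 1:
        raise ConfigurationError("scenarios.glide_fraction: must lie in [0, 1)")
    geo = config.get("geometry", {})
    if geo.get("fork_length", 1) <= 0:
        raise ConfigurationError("geometry.fork_length: must be > 0")


def fluid_from_config(config: Mapping[str, Any]) -> FluidProperties:
    f = config["fluid"]
    return FluidProperties(
        density=f["density"], dynamic_viscosity=f["dynamic_viscosity"]
    )


def geometry_from_config(config: Mapping[str, Any]) -> SharkGeometry:
    g = config["geometry"]
    area = g.get("frontal_area")
    if area is None and "area_coefficient" in g:
        area = g["area_coefficient"] * g["fork_length"] ** 2
    return SharkGeometry(fork_length=g["fork_length"], frontal_area=area)


def mass_model_from_config(config: Mapping[str, Any]) -> MassModel:
    m = config["mass_model"]
    return MassModel(
        anchor_length=m["anchor_length"],
        anchor_mass=m["anchor_mass"],
        exponent=m["exponent"],
    )
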