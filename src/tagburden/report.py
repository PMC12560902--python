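"""Tag-impact reference tables and the end-to-end assessment pipeline.

The reference table is the practitioner-facing product: one row per
(fork length, swim speed, tag configuration) with the untagged and tagged
drag coefficients, the percent drag increase, the percent daily-energy
increase under a reference activity budget, and the equal-power
burst-speed reduction in both variants.  Rows a supplied table cannot
cover (e.g. fin-mount data exist only for the full-size shark) are flagged
with missing values, or raise in strict mode.
"""

from __future__ import annotations

import logging
import sys
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .config import fluid_from_config, geometry_from_config, load_config
from .dragtable import (
    DragCoefficientTable,
    lookup_cd,
    packaged_drag_tables,
    read_drag_tables,
)
from .energetics import build_budget, energy_increase, scenario_grid
from .errors import RangeError
from .forces import percent_increase
from .performance import burst_speed_reduction
from .physics import FluidProperties, SharkGeometry, scale_geometry

logger = logging.getLogger(__name__)

#: Burst-time share of the reference budget used for the energy column.
REFERENCE_BURST_FRACTION = 0.05

_REPORT_COLUMNS = [
    "size_m",
    "speed_m_s",
    "tag_config",
    "cd_untagged",
    "cd_tagged",
    "pct_drag_increase",
    "pct_energy_increase",
    "pct_speed_reduction_fixed_force",
    "pct_speed_reduction_cd_interpolated",
]


def reference_table(
    sizes: Sequence[float],
    speeds: Sequence[float],
    configs: Sequence[str],
    tables: Mapping[str, DragCoefficientTable],
    fluid: FluidProperties,
    geometry: Optional[SharkGeometry] = None,
    *,
    strict: bool = False,
) -> pd.DataFrame:
    """Reference table of tag impacts, ordered by size, speed, then config.

    The energy column uses a reference budget bursting 5% of the day at
    the row's speed (cruise 1 m/s, glide 7%); rows whose speed is below
    the cruise speed leave the energy and speed-reduction columns empty,
    as no valid budget can burst slower than it cruises.
    """
    if geometry is None:
        geometry = SharkGeometry(fork_length=max(sizes) if len(sizes) else 1.0)
    untagged = tables["none"]
    rows: list[dict[str, Any]] = []
    for size in sizes:
        geom = scale_geometry(geometry, size)
        for speed in speeds:
            for config in configs:
                row: dict[str, Any] = {
                    "size_m": size,
                    "speed_m_s": speed,
                    "tag_config": config,
                }
                tagged = tables.get(config)
                try:
                    if tagged is None:
                        raise RangeError(f"no drag table for config {config!r}")
                    cd_u = lookup_cd(untagged, size, speed, clamp=False)
                    cd_t = lookup_cd(tagged, size, speed, clamp=False)
                    row["cd_untagged"] = cd_u
                    row["cd_tagged"] = cd_t
                    row["pct_drag_increase"] = percent_increase(cd_u, cd_t)
                    if speed >= 1.0:
                        budget = build_budget(REFERENCE_BURST_FRACTION, speed)
                        row["pct_energy_increase"] = energy_increase(
                            budget, untagged, tagged, fluid, geom, clamp=False
                        )
                        for variant in ("fixed_force", "cd_interpolated"):
                            red = burst_speed_reduction(
                                speed, untagged, tagged, fluid, geom, variant
                            )
                            row[f"pct_speed_reduction_{variant}"] = (
                                red.reduction_percent
                            )
                except RangeError as exc:
                    if strict:
                        raise
                    logger.warning(
                        "reference row (%s m, %s m/s, %s) not covered: %s",
                        size,
                        speed,
                        config,
                        exc,
                    )
                rows.append(row)
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return round(x, sig - 1 - int(np.floor(np.log10(abs(x)))))


def format_reference_table(report: pd.DataFrame) -> str:
    """Aligned human-readable rendering: C_D to 3 significant figures,
    percentages to 1 decimal (matching print conventions for such tables)."""
    shown = report.copy()
    for col in ("cd_untagged", "cd_tagged"):
        shown[col] = shown[col].map(lambda x: _round_sig(x, 3))
    for col in shown.columns:
        if col.startswith("pct_"):
            shown[col] = shown[col].round(1)
    return shown.to_string(index=False, na_rep="-")


def run_pipeline(
    config_path: Optional[Union[str, Path]],
    out_dir: Union[str, Path] = "tagburden_out",
    *,
    strict: bool = False,
) -> dict[str, Path]:
    """Run scenarios, reference table and speed reductions from a config.

    Writes ``scenarios.csv``, ``reference_table.csv`` (raw precision),
    ``reference_table.txt`` (rounded), ``speed_reductions.csv`` and
    ``run_log.txt`` (config echo, package version, timestamp) under
    ``out_dir``.  All output files except the log are deterministic for a
    fixed config.
    """
    config = load_config(config_path)
    fluid = fluid_from_config(config)
    geometry = geometry_from_config(config)
    if config.get("drag_table"):
        tables = read_drag_tables(config["drag_table"])
    else:
        tables = packaged_drag_tables()
    untagged = tables["none"]
    sc = config["scenarios"]

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    grids = []
    reductions = []
    for config_label in config["tag_configs"]:
        tagged = tables[config_label]
        size_ok = (
            tagged.size_range[0] <= geometry.fork_length <= tagged.size_range[1]
        )
        if not size_ok and strict:
            raise RangeError(
                f"{config_label}: no coverage at {geometry.fork_length} m"
            )
        if not size_ok:
            logger.warning(
                "%s: clamping size %.3g m to table coverage",
                config_label,
                geometry.fork_length,
            )
        grids.append(
            scenario_grid(
                untagged,
                tagged,
                fluid,
                geometry,
                burst_speeds=sc["burst_speeds"],
                burst_fractions=sc["burst_fractions"],
                cruise_speed=sc["cruise_speed"],
                glide_fraction=sc["glide_fraction"],
            )
        )
        for variant in ("fixed_force", "cd_interpolated"):
            for vb in sc["burst_speeds"]:
                red = burst_speed_reduction(
                    vb, untagged, tagged, fluid, geometry, variant
                )
                reductions.append(
                    {
                        "variant": variant,
                        "tag_config": config_label,
                        "burst_speed": vb,
                        "reduced_speed": red.reduced_speed,
                        "pct_reduction": red.reduction_percent,
                    }
                )

    scenarios = pd.concat(grids, ignore_index=True)
    report = reference_table(
        sorted(set(untagged.sizes.tolist()) | {geometry.fork_length}),
        untagged.speeds.tolist(),
        config["tag_configs"],
        tables,
        fluid,
        geometry,
        strict=strict,
    )

    paths = {
        "scenarios": out / "scenarios.csv",
        "reference_csv": out / "reference_table.csv",
        "reference_txt": out / "reference_table.txt",
        "reductions": out / "speed_reductions.csv",
        "log": out / "run_log.txt",
    }
    scenarios.to_csv(paths["scenarios"], index=False)
    report.to_csv(paths["reference_csv"], index=False)
    paths["reference_txt"].write_text(
        format_reference_table(report) + "\n", encoding="utf-8"
    )
    pd.DataFrame(reductions).to_csv(paths["reductions"], index=False)

    import yaml as _yaml

    paths["log"].write_text(
        f"tagburden {__version__}\n"
        f"run at {datetime.now(timezone.utc).isoformat()}\n"
        f"python {sys.version.split()[0]}\n"
        "--- config ---\n" + _yaml.safe_dump(config, sort_keys=True),
        encoding="utf-8",
    )
    return paths
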