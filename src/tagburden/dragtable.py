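"""Drag-coefficient tables on a (speed x fork-length) grid, with lookup.

The package ships the drag coefficients of tagged and untagged mako sharks
obtained from steady RANS simulations: untagged and archival-tagged sharks
at five fork lengths (1, 1.5, 2, 2.5, 2.95 m) and a fin-mounted tag at
2.95 m only, each over eight swim speeds from 0.5 to 9.1 m/s.

Between grid knots, lookup is log-log linear in speed (drag coefficients
decay approximately as a power law in Reynolds number, hence in speed at
fixed size) and linear in fork length.  The interpolant is exact at every
knot and monotone-preserving on monotone columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import InvalidInputError, RangeError
from .physics import TagKind

logger = logging.getLogger(__name__)

#: Column order of the drag-table CSV dialect.
CSV_COLUMNS = ("speed_m_s", "fork_length_m", "tag_config", "cd")


@dataclass(frozen=True)
class DragCoefficientTable:
    """C_D values on a strictly increasing (speed, size) grid.

    ``values[i, j]`` is the drag coefficient at ``speeds[i]`` and
    ``sizes[j]``.  All cells must be positive; speeds and sizes strictly
    increasing.
    """

    speeds: np.ndarray
    sizes: np.ndarray
    values: np.ndarray
    config: str = TagKind.NONE.value

    def __post_init__(self) -> None:
        object.__setattr__(self, "speeds", np.asarray(self.speeds, dtype=float))
        object.__setattr__(self, "sizes", np.asarray(self.sizes, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.speeds.ndim != 1 or self.sizes.ndim != 1:
            raise InvalidInputError("speeds and sizes must be 1-D")
        if self.values.shape != (self.speeds.size, self.sizes.size):
            raise InvalidInputError(
                f"values shape {self.values.shape} does not match "
                f"({self.speeds.size}, {self.sizes.size})"
            )
        if np.any(np.diff(self.speeds) <= 0):
            raise InvalidInputError("speeds must be strictly increasing")
        if np.any(np.diff(self.sizes) <= 0):
            raise InvalidInputError("sizes must be strictly increasing")
        if np.any(self.speeds <= 0):
            raise InvalidInputError("table speeds must be > 0")
        if not np.all(self.values > 0):
            raise InvalidInputError("every C_D cell must be > 0")

    @property
    def speed_range(self) -> tuple[float, float]:
        return float(self.speeds[0]), float(self.speeds[-1])

    @property
    def size_range(self) -> tuple[float, float]:
        return float(self.sizes[0]), float(self.sizes[-1])

    def column(self, size: float) -> np.ndarray:
        """The C_D column at an exact grid size."""
        j = np.flatnonzero(np.isclose(self.sizes, size))
        if j.size == 0:
            raise RangeError(f"size {size} is not a grid knot of this table")
        return self.values[:, j[0]]

    def is_monotone_decreasing(self) -> bool:
        """True when every size column is non-increasing in speed."""
        return bool(np.all(np.diff(self.values, axis=0) <= 0))

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form frame in the package's CSV dialect."""
        speed, size = np.meshgrid(self.speeds, self.sizes, indexing="ij")
        return pd.DataFrame(
            {
                "speed_m_s": speed.ravel(),
                "fork_length_m": size.ravel(),
                "tag_config": self.config,
                "cd": self.values.ravel(),
            }
        )


def lookup_cd(
    table: DragCoefficientTable,
    size: float,
    speed: float,
    *,
    clamp: bool = True,
) -> float:
    """Interpolated drag coefficient at (fork length, speed).

    Log-log linear in speed, then linear in fork length; exact at grid
    knots.  Out-of-range queries are clamped to the table edge with a
    logged warning when ``clamp`` is true, and raise ``RangeError`` when
    it is false.
    """
    if speed <= 0 or size <= 0:
        raise InvalidInputError("size and speed must be > 0 for lookup")
    lo_u, hi_u = table.speed_range
    lo_l, hi_l = table.size_range
    if not (lo_u <= speed <= hi_u) or not (lo_l <= size <= hi_l):
        if not clamp:
            raise RangeError(
                f"query (size={size} m, speed={speed} m/s) outside table "
                f"coverage [{lo_l}, {hi_l}] m x [{lo_u}, {hi_u}] m/s"
            )
        logger.warning(
            "clamping query (size=%s m, speed=%s m/s) to table edge", size, speed
        )
        speed = min(max(speed, lo_u), hi_u)
        size = min(max(size, lo_l), hi_l)

    log_speed = np.log(table.speeds)
    # per-size-column log-log interpolation in speed
    cols = np.exp(
        [
            np.interp(np.log(speed), log_speed, np.log(table.values[:, j]))
            for j in range(table.sizes.size)
        ]
    )
    return float(np.interp(size, table.sizes, cols))


def _frame_to_tables(frame: pd.DataFrame) -> dict[str, DragCoefficientTable]:
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise InvalidInputError(f"drag-table CSV missing columns: {sorted(missing)}")
    out: dict[str, DragCoefficientTable] = {}
    for config, sub in frame.groupby("tag_config", sort=False):
        wide = sub.pivot_table(
            index="speed_m_s", columns="fork_length_m", values="cd"
        )
        if wide.isna().any().any():
            raise InvalidInputError(
                f"config {config!r}: (speed, size) grid has missing cells"
            )
        out[str(config)] = DragCoefficientTable(
            speeds=wide.index.to_numpy(),
            sizes=wide.columns.to_numpy(),
            values=wide.to_numpy(),
            config=str(config),
        )
    return out


def read_drag_tables(path_or_buffer) -> dict[str, DragCoefficientTable]:
    """Read a drag-table CSV (one table per ``tag_config`` label).

    Dialect: header ``speed_m_s, fork_length_m, tag_config, cd``, dot
    decimal separator, UTF-8.  Each (size, config) column must form a
    complete, strictly increasing speed grid.
    """
    frame = pd.read_csv(path_or_buffer)
    return _frame_to_tables(frame)


def write_drag_tables(
    tables: Union[DragCoefficientTable, Iterable[DragCoefficientTable]], path
) -> None:
    """Write one or more tables in the standard CSV dialect."""
    if isinstance(tables, DragCoefficientTable):
        tables = [tables]
    frame = pd.concat([t.to_dataframe() for t in tables], ignore_index=True)
    frame.to_csv(path, index=False)


def packaged_drag_tables() -> dict[str, DragCoefficientTable]:
    """The simulated coefficient tables shipped with the package.

    Keys are tag-config labels: ``none``, ``archival_body`` (body-pinned
    pop-up archival tag at site 3; all four sites share this column) and
    ``fin_mount`` (dorsal-fin transmitter, 2.95 m shark only).
    """
    ref = resources.files("tagburden.data").joinpath("table2_cd.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return read_drag_tables(fh)


def packaged_speed_table() -> pd.DataFrame:
    """The modelled swim speeds and their published Reynolds numbers."""
    ref = resources.files("tagburden.data").joinpath("table1_speeds.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)
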