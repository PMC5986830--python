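"""Three-axis experimental data cube and series extraction.

Every peaklist sits at a coordinate (z, y, x) of a dense three-axis grid:
each axis represents one experimental variable (e.g. x = ligand
concentration, y = protein construct, z = diamagnetic/paramagnetic).  A
*series* is the ordered run of peaklists along one axis at fixed values of
the other two; its first element is the reference experiment.

Axis policy
-----------
Some analyses are restricted to specific axes: paramagnetic (ΔPRE) analysis
runs only along z, different protein sequences may differ only along y, and
fitting of continuous data runs only along x.  :func:`axis_policy_check`
enforces this before any computation starts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .peaklist_io import PeaklistTable

logger = logging.getLogger(__name__)

AXES = ("x", "y", "z")

#: analysis kind -> axes on which it is permitted
AXIS_POLICY: dict[str, tuple[str, ...]] = {
    "csp": ("x", "y", "z"),
    "height_ratio": ("x", "y", "z"),
    "volume_ratio": ("x", "y", "z"),
    "dpre": ("z",),
    "fitting": ("x",),
    "sequence_variation": ("y",),
}


class CubeError(Exception):
    """Cube construction or policy violation."""


class AxisPolicyError(CubeError):
    """An analysis was requested along a forbidden axis."""


@dataclass(frozen=True)
class AxisSpec:
    """One axis of the cube: identity plus ordered condition labels.

    Labels are stored as text; for the x axis a numeric value per label is
    parsed once at construction (needed for fitting).  Non-numeric labels
    simply disable fitting, they are not an error.
    """

    axis: str
    labels: tuple[str, ...]
    numeric_values: tuple[float, ...] | None = field(default=None)

    def __post_init__(self):
        if self.axis not in AXES:
            raise CubeError(f"axis must be one of {AXES}, got {self.axis!r}")
        if len(self.labels) < 1:
            raise CubeError(f"axis {self.axis!r} needs at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise CubeError(f"axis {self.axis!r} labels are not unique")
        if self.numeric_values is None:
            try:
                vals = tuple(float(lbl) for lbl in self.labels)
            except ValueError:
                vals = None
            object.__setattr__(self, "numeric_values", vals)
        if self.numeric_values is not None:
            diffs = [b - a for a, b in
                     zip(self.numeric_values, self.numeric_values[1:])]
            if any(d <= 0 for d in diffs):
                raise CubeError(
                    f"numeric labels on axis {self.axis!r} must be strictly "
                    f"increasing: {self.labels}"
                )

    @property
    def is_numeric(self) -> bool:
        return self.numeric_values is not None

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class Series:
    """Ordered peaklists along one axis at fixed other-axis coordinates."""

    along: str
    fixed: dict[str, str]          # the two fixed axes -> their labels
    labels: tuple[str, ...]        # along-axis labels, in axis order
    tables: list[PeaklistTable]
    numeric_values: tuple[float, ...] | None = None

    def __post_init__(self):
        if len(self.labels) != len(self.tables):
            raise CubeError("series labels/tables length mismatch")

    @property
    def reference(self) -> PeaklistTable:
        """The reference experiment: always the first in the series."""
        return self.tables[0]

    def __len__(self) -> int:
        return len(self.tables)

    def __iter__(self):
        return iter(self.tables)

    @property
    def coordinate_id(self) -> str:
        """Stable identifier, e.g. ``along_x__z=dia__y=wt``."""
        fixed = "__".join(f"{a}={self.fixed[a]}" for a in AXES
                          if a in self.fixed)
        return f"along_{self.along}__{fixed}"


class Cube:
    """Dense mapping from (z, y, x) label triples to peaklists.

    Construction requires exactly one table per coordinate combination;
    sparse cubes are rejected.  Insertion order never matters: cell and
    series order follow the axis label order.
    """

    def __init__(
        self,
        axes: Mapping[str, AxisSpec],
        cells: Mapping[tuple[str, str, str], PeaklistTable],
    ):
        if set(axes) != set(AXES):
            raise CubeError(f"need axes {AXES}, got {sorted(axes)}")
        self.axes = dict(axes)
        expected = {
            (z, y, x)
            for z in axes["z"].labels
            for y in axes["y"].labels
            for x in axes["x"].labels
        }
        got = set(cells)
        missing = expected - got
        extra = got - expected
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"missing coordinates: {sorted(missing)[:5]}")
            if extra:
                parts.append(f"unknown coordinates: {sorted(extra)[:5]}")
            raise CubeError("; ".join(parts))
        self.cells: dict[tuple[str, str, str], PeaklistTable] = {}
        for z, y, x in sorted(expected):
            table = cells[(z, y, x)]
            table.coordinate = (z, y, x)
            self.cells[(z, y, x)] = table

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def shape(self) -> tuple[int, int, int]:
        """(|x|, |y|, |z|)."""
        return (len(self.axes["x"]), len(self.axes["y"]),
                len(self.axes["z"]))

    def __getitem__(self, key: tuple[str, str, str]) -> PeaklistTable:
        return self.cells[key]


def build_cube(
    peaklists: Mapping[tuple[str, str, str], PeaklistTable],
    axes: Sequence[AxisSpec] | Mapping[str, AxisSpec],
) -> Cube:
    """Assemble a :class:`Cube` from labelled peaklists.

    ``peaklists`` maps (z, y, x) label triples to tables; ``axes`` gives the
    three :class:`AxisSpec` (any order).  Missing or duplicate coordinates
    raise :class:`CubeError` naming the offenders.
    """
    if not isinstance(axes, Mapping):
        axes = {spec.axis: spec for spec in axes}
        if len(axes) != 3:
            raise CubeError("three distinct axes (x, y, z) are required")
    return Cube(axes, peaklists)


def enumerate_series(cube: Cube, along: str) -> list[Series]:
    """All series along one axis: one per combination of the other two axes.

    The result has exactly ``len(other1) * len(other2)`` series; every cell
    of the cube appears in exactly one of them.  Axes of length 1 yield
    single-point series with a logged notice (nothing to compare).
    """
    if along not in AXES:
        raise CubeError(f"unknown axis {along!r}")
    if len(cube.axes[along]) == 1:
        logger.info(
            "axis %r has a single point: series of length 1 (nothing to "
            "compare)", along,
        )
    others = [a for a in AXES if a != along]
    out: list[Series] = []
    for combo in itertools.product(
        *(cube.axes[a].labels for a in others)
    ):
        fixed = dict(zip(others, combo))
        tables = []
        for lbl in cube.axes[along].labels:
            coord = {along: lbl, **fixed}
            tables.append(cube.cells[(coord["z"], coord["y"], coord["x"])])
        out.append(Series(
            along=along,
            fixed=fixed,
            labels=cube.axes[along].labels,
            tables=tables,
            numeric_values=cube.axes[along].numeric_values,
        ))
    return out


def axis_policy_check(
    cube: Cube, requested: Iterable[tuple[str, str]]
) -> list[tuple[str, str]]:
    """Validate requested (analysis, axis) pairs against the axis policy.

    Returns the validated plan; raises :class:`AxisPolicyError` listing every
    violation before any computation runs.  Fitting additionally requires a
    numeric x axis.
    """
    plan: list[tuple[str, str]] = []
    violations: list[str] = []
    for analysis, axis in requested:
        if analysis not in AXIS_POLICY:
            violations.append(f"unknown analysis {analysis!r}")
            continue
        allowed = AXIS_POLICY[analysis]
        if axis not in allowed:
            violations.append(
                f"{analysis!r} requested along {axis!r} but is only "
                f"permitted along {'/'.join(allowed)} (paramagnetic analysis "
                f"only along z, sequence variation only along y, fitting of "
                f"continuous data only along x)"
            )
            continue
        if analysis == "fitting" and not cube.axes["x"].is_numeric:
            violations.append(
                "fitting requires numeric x-axis labels; got "
                f"{cube.axes['x'].labels}"
            )
            continue
        plan.append((analysis, axis))
    if violations:
        raise AxisPolicyError("; ".join(violations))
    return plan
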