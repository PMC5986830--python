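"""Comparative/stacking analysis across cube axes.

A parameter computed along one axis (say ΔPRE along z, one value per
residue per z-series) often needs to be *presented* along another axis
(e.g. as a residues × sequence-variant heat map, or per-residue curves
against ligand concentration).  Stacking is pure re-indexing: every cell of
a :class:`ComparativeTable` is numerically identical to exactly one source
cell, and the provenance mapping makes the operation invertible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cube import AXES, Series
from .peaklist_io import ResultTable

logger = logging.getLogger(__name__)


class ComparativeError(Exception):
    pass


@dataclass
class ComparativeTable:
    """Residues × presented-axis-labels matrix of one derived parameter.

    ``provenance`` maps each column label to the coordinate of the source
    :class:`ResultTable` the values were lifted from.
    """

    parameter: str
    computed_along: str
    presented_along: str
    matrix: pd.DataFrame
    provenance: dict[str, tuple] = field(default_factory=dict)

    def unstack_column(self, label: str) -> pd.Series:
        """Recover one source column (the inverse of stacking)."""
        return self.matrix[label]


def stack(
    sources: dict[str, ResultTable],
    parameter: str,
    computed_along: str,
    presented_along: str,
) -> ComparativeTable:
    """Regroup one parameter from several result tables into a matrix.

    ``sources`` maps presented-axis labels (in axis order) to the result
    table holding the parameter for that label.  Residue sets may differ
    between labels (different sequences on y): the join is outer, absent
    residues become NaN, and an alignment report is logged.
    """
    if not sources:
        raise ComparativeError("nothing to stack")
    cols: dict[str, pd.Series] = {}
    prov: dict[str, tuple] = {}
    for label, table in sources.items():
        if parameter not in table.frame.columns:
            raise ComparativeError(
                f"parameter {parameter!r} absent from source for {label!r}"
            )
        cols[label] = table.frame.set_index("residue_number")[parameter]
        prov[label] = table.coordinate
    matrix = pd.DataFrame(cols)  # outer join on residue number
    counts = matrix.notna().sum(axis=1)
    partial = matrix.index[(counts > 0) & (counts < len(cols))]
    if len(partial) and len(cols) > 1:
        logger.info(
            "alignment report: %d residues present in fewer than all %d "
            "columns (e.g. %s)", len(partial), len(cols),
            list(partial[:5]),
        )
    matrix.index.name = "residue_number"
    return ComparativeTable(
        parameter=parameter,
        computed_along=computed_along,
        presented_along=presented_along,
        matrix=matrix,
        provenance=prov,
    )


def compare_across(
    series_results: dict[tuple, list[ResultTable]],
    series_list: list[Series],
    parameter: str,
    present_along: str,
    point_label: str | None = None,
) -> list[ComparativeTable]:
    """Stack one parameter from all series of an axis along another axis.

    ``series_results`` maps each series' fixed-coordinate tuple (as given by
    ``tuple(sorted(series.fixed.items()))``) to its computed result tables.
    The parameter value for a series is taken from its *last* table unless
    ``point_label`` selects a specific series point.  One
    :class:`ComparativeTable` is produced per label of the remaining axis.
    """
    if not series_list:
        return []
    computed_along = series_list[0].along
    if present_along == computed_along:
        raise ComparativeError(
            "presentation axis must differ from the computation axis"
        )
    remaining = [a for a in AXES
                 if a not in (computed_along, present_along)][0]
    groups: dict[str, dict[str, ResultTable]] = {}
    for series in series_list:
        key = tuple(sorted(series.fixed.items()))
        results = series_results[key]
        if point_label is not None:
            idx = list(series.labels).index(point_label)
        else:
            idx = len(series.labels) - 1
        table = results[idx]
        groups.setdefault(series.fixed[remaining], {})[
            series.fixed[present_along]] = table
    out = []
    for rem_label, sources in sorted(groups.items()):
        if len(sources) == 1 and len(groups) == 1:
            logger.info(
                "single-label comparison along %s: no-op stacking",
                present_along,
            )
        out.append(stack(sources, parameter, computed_along, present_along))
    return out


def write_stacked_csv(table: ComparativeTable, path) -> None:
    """Write ``<parameter>_stacked_<axis>.csv``-style matrix output."""
    table.matrix.to_csv(path)
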