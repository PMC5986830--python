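"""Series curation: missing/unassigned residue detection and row padding.

Along an experimental series a peak may vanish (exchange broadening at a
given titration point) or a residue may never have been assigned at all.
These are very different situations and must stay distinguishable:

* *missing*  -- observed earlier in the series, gone at this point; under
  the ``carry_last`` fill policy the last measured values are kept so the
  residue still appears in plots (coloured red).
* *unassigned* -- no peak anywhere in the series (prolines, unassigned
  stretches); rows are created as empty placeholders (grey in plots).

After :func:`pad_tables` every table of a series has the same residue index
and row count, which is what downstream per-residue arithmetic relies on.
The scan runs along the x axis only; y/z analyses reuse the normalized
tables.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cube import Series
from .peaklist_io import (
    AA1,
    CANONICAL_COLUMNS,
    STATUS_MEASURED,
    STATUS_MISSING,
    STATUS_UNASSIGNED,
    PeakRow,
    PeaklistTable,
)

logger = logging.getLogger(__name__)

_SIDECHAIN_RE = re.compile(r"[ab]$")


class CurationError(Exception):
    pass


@dataclass
class SeriesScan:
    """Result of :func:`scan_series`.

    ``statuses``: residue × series-point DataFrame of status strings.
    ``filled_from``: same shape; for *missing* cells, the label of the last
    measured point whose values are carried (None when no earlier
    observation exists).  ``residue_types``: best-known one-letter code per
    residue ("" if unknown).
    """

    universe: tuple[int, ...]
    statuses: pd.DataFrame
    filled_from: pd.DataFrame
    residue_types: dict[int, str]

    def counts(self, label: str) -> dict[str, int]:
        col = self.statuses[label]
        return {s: int((col == s).sum())
                for s in (STATUS_MEASURED, STATUS_MISSING, STATUS_UNASSIGNED)}


# ---------------------------------------------------------------------------
# sequence input

def parse_sequence_spec(spec: str | Path) -> dict[int, str]:
    """Residue universe from a FASTA file or a ``first:last`` range.

    A FASTA file must hold a single record; numbering starts at 1 unless the
    header carries ``start=<n>``.  A range spec like ``"5:104"`` yields
    residues 5..104 with unknown types.
    """
    text = None
    if isinstance(spec, Path) or (isinstance(spec, str)
                                  and Path(spec).is_file()):
        text = Path(spec).read_text()
    elif isinstance(spec, str) and spec.lstrip().startswith(">"):
        text = spec
    if text is not None:
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        if not lines or not lines[0].startswith(">"):
            raise CurationError("FASTA sequence must start with a '>' header")
        if any(ln.startswith(">") for ln in lines[1:]):
            raise CurationError("FASTA sequence must hold a single record")
        m = re.search(r"start=(\d+)", lines[0])
        start = int(m.group(1)) if m else 1
        seq = "".join(lines[1:]).upper()
        bad = set(seq) - AA1
        if bad:
            raise CurationError(f"non-canonical residue codes: {sorted(bad)}")
        return {start + i: aa for i, aa in enumerate(seq)}
    m = re.match(r"^\s*(\d+)\s*:\s*(\d+)\s*$", str(spec))
    if not m:
        raise CurationError(
            f"sequence spec {spec!r} is neither a FASTA file nor first:last"
        )
    first, last = int(m.group(1)), int(m.group(2))
    if last < first:
        raise CurationError("sequence range end precedes start")
    return {i: "" for i in range(first, last + 1)}


# ---------------------------------------------------------------------------
# scan

def _measured_mask(frame: pd.DataFrame) -> pd.Series:
    return (
        (frame["status"] == STATUS_MEASURED)
        & frame["shift_f1"].notna()
        & frame["shift_f2"].notna()
    )


def scan_series(
    series: Series, sequence: dict[int, str] | None = None
) -> SeriesScan:
    """Classify every residue at every series point.

    The residue universe is the supplied ``sequence`` (residue -> one-letter
    type) or, absent one, the union of residues over the series.  A residue
    carrying two conflicting backbone rows in one table is a curation error.
    """
    labels = list(series.labels)
    observed_at: dict[int, list[int]] = {}
    types: dict[int, str] = dict(sequence or {})
    for i, (label, table) in enumerate(zip(labels, series.tables)):
        frame = table.frame
        backbone = frame[~(
            frame["atom_f1"].str.contains(_SIDECHAIN_RE, regex=True)
            | frame["atom_f2"].str.contains(_SIDECHAIN_RE, regex=True)
        )]
        dup = backbone["residue_number"].duplicated(keep=False)
        if dup.any():
            offenders = backbone.loc[dup, "residue_number"]
            conflicting = sorted(set(offenders))
            raise CurationError(
                f"conflicting backbone rows for residues {conflicting} in "
                f"{table.source_path or label!r}"
            )
        meas = backbone[_measured_mask(backbone)]
        for num, rtype in zip(meas["residue_number"], meas["residue_type"]):
            observed_at.setdefault(int(num), []).append(i)
            if rtype and not types.get(int(num)):
                types[int(num)] = rtype
    universe = sorted(set(observed_at) | set(sequence or {}))
    if not universe:
        raise CurationError("series contains no residues at all")
    statuses = pd.DataFrame(
        STATUS_UNASSIGNED, index=universe, columns=labels, dtype=object
    )
    filled = pd.DataFrame(None, index=universe, columns=labels, dtype=object)
    for num, points in observed_at.items():
        pts = set(points)
        last_measured: int | None = None
        for i, label in enumerate(labels):
            if i in pts:
                statuses.at[num, label] = STATUS_MEASURED
                last_measured = i
            else:
                statuses.at[num, label] = STATUS_MISSING
                if last_measured is not None:
                    filled.at[num, label] = labels[last_measured]
    return SeriesScan(
        universe=tuple(universe),
        statuses=statuses,
        filled_from=filled,
        residue_types={n: types.get(n, "") for n in universe},
    )


# ---------------------------------------------------------------------------
# padding

_CARRY_COLUMNS = [
    "residue_type", "atom_f1", "atom_f2", "shift_f1", "shift_f2",
    "height", "volume", "linewidth_f1", "linewidth_f2",
]


def pad_tables(
    series: Series,
    scan: SeriesScan | None = None,
    fill_policy: str = "carry_last",
) -> Series:
    """Normalize every table of a series to the common residue index.

    ``fill_policy='carry_last'`` copies the last measured values into
    *missing* rows (causal: never from a later point); ``'blank'`` leaves
    their observables empty.  Unassigned rows are always empty placeholders.
    Idempotent: padding an already-padded series changes nothing.
    """
    if fill_policy not in ("carry_last", "blank"):
        raise CurationError(f"unknown fill policy {fill_policy!r}")
    if scan is None:
        scan = scan_series(series)
    labels = list(series.labels)
    by_label = {
        lbl: t.frame.set_index("residue_number", drop=False)
        for lbl, t in zip(labels, series.tables)
    }
    new_tables: list[PeaklistTable] = []
    for lbl, table in zip(labels, series.tables):
        frame = by_label[lbl]
        records: list[dict] = []
        for num in scan.universe:
            status = scan.statuses.at[num, lbl]
            if status == STATUS_MEASURED:
                rec = frame.loc[num].to_dict()
                rec["status"] = STATUS_MEASURED
            elif status == STATUS_MISSING:
                rec = {c: (math.nan if c not in
                           ("residue_type", "atom_f1", "atom_f2")
                           else "")
                       for c in _CARRY_COLUMNS}
                src_lbl = scan.filled_from.at[num, lbl]
                if fill_policy == "carry_last" and isinstance(src_lbl, str):
                    src = by_label[src_lbl].loc[num]
                    rec = {c: src[c] for c in _CARRY_COLUMNS}
                rec.update(
                    residue_number=num,
                    residue_type=rec.get("residue_type")
                    or scan.residue_types[num],
                    merit="", details="", fit_method="",
                    status=STATUS_MISSING,
                )
            else:  # unassigned placeholder
                rec = dict(
                    residue_number=num,
                    residue_type=scan.residue_types[num],
                    atom_f1="", atom_f2="",
                    shift_f1=math.nan, shift_f2=math.nan,
                    height=math.nan, volume=math.nan,
                    linewidth_f1=math.nan, linewidth_f2=math.nan,
                    merit="", details="", fit_method="",
                    status=STATUS_UNASSIGNED,
                )
            rec = {k: rec.get(k) for k in CANONICAL_COLUMNS}
            rec["residue_number"] = num
            records.append(rec)
        new = PeaklistTable(
            pd.DataFrame.from_records(records, columns=CANONICAL_COLUMNS),
        )
        new.source_path = table.source_path
        new.source_format = table.source_format
        new.coordinate = table.coordinate
        new_tables.append(new)
    return Series(
        along=series.along,
        fixed=series.fixed,
        labels=series.labels,
        tables=new_tables,
        numeric_values=series.numeric_values,
    )


# ---------------------------------------------------------------------------
# sidechains

def tag_sidechains(
    table: PeaklistTable, keep: bool = True
) -> tuple[PeaklistTable, PeaklistTable | None]:
    """Split NH2 sidechain rows (atom names ending 'a'/'b') from backbone.

    Returns ``(backbone_table, sidechain_table)``; the sidechain table is
    ``None`` when ``keep`` is off, in which case the dropped count is
    logged.
    """
    frame = table.frame
    mask = (
        frame["atom_f1"].str.contains(_SIDECHAIN_RE, regex=True)
        | frame["atom_f2"].str.contains(_SIDECHAIN_RE, regex=True)
    )
    backbone = table.replace_frame(frame[~mask].reset_index(drop=True))
    n_side = int(mask.sum())
    if not keep:
        if n_side:
            logger.info(
                "dropped %d sidechain rows from %s", n_side,
                table.source_path or "<table>",
            )
        return backbone, None
    sidechain = table.replace_frame(frame[mask].reset_index(drop=True))
    return backbone, sidechain
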