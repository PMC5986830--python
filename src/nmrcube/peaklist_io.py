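"""Peaklist readers and the canonical table model.

2D heteronuclear peaklists (one backbone-amide peak per residue, plus
possible NH2 sidechain entries) are exported by every major NMR assignment
program in a different tabular dialect.  This module parses the supported
dialects -- Sparky list files, NMRPipe ``.tab`` tables, CCPN Analysis v2
tabular exports and NmrView ``.xpk`` files -- into a single canonical
:class:`PeaklistTable`, and writes/reads a canonical comma-separated
representation that round-trips losslessly.

The Ansig fixed-width dialect is recognised as a name but not parsed.

Conventions
-----------
* ``f1`` is the heteronucleus dimension (15N, ppm), ``f2`` the 1H dimension.
* Assignment strings follow the grammar
  ``<1-letter code><residue number><atom_f1>-<atom_f2>`` (e.g. ``T103N-H``)
  or ``<3-letter code><residue number><atom>`` (e.g. ``Gly45N``).
  Anything else is a parse error: failing loudly beats misassigning a peak.
* Absent optional columns stay empty (NaN / ``""``); no value is invented.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# constants

SUPPORTED_FORMATS = ("sparky", "nmrpipe", "ccpnv2", "nmrview", "ansig")

#: canonical CSV column order; derived columns are appended after these
CANONICAL_COLUMNS = [
    "residue_number",
    "residue_type",
    "atom_f1",
    "atom_f2",
    "shift_f1",
    "shift_f2",
    "height",
    "volume",
    "linewidth_f1",
    "linewidth_f2",
    "merit",
    "details",
    "fit_method",
    "status",
]

_FLOAT_COLUMNS = {
    "shift_f1", "shift_f2", "height", "volume", "linewidth_f1", "linewidth_f2",
}
_TEXT_COLUMNS = {
    "residue_type", "atom_f1", "atom_f2", "merit", "details", "fit_method",
    "status",
}

STATUS_MEASURED = "measured"
STATUS_MISSING = "missing"
STATUS_UNASSIGNED = "unassigned"
STATUSES = (STATUS_MEASURED, STATUS_MISSING, STATUS_UNASSIGNED)

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
AA1 = set(AA3_TO_1.values())
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


# ---------------------------------------------------------------------------
# errors

class PeaklistError(Exception):
    """Base class for peaklist I/O failures."""


class UnrecognizedFormatError(PeaklistError):
    """Content matched none of the known dialects."""

    def __init__(self, closest: str):
        self.closest = closest
        super().__init__(
            f"unrecognized format (closest candidate: {closest!r})"
        )


class UnsupportedDialectError(PeaklistError):
    """Dialect is named but intentionally not implemented (Ansig)."""


class PeaklistParseError(PeaklistError):
    """Malformed peak line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class AssignmentGrammarError(PeaklistError):
    """Assignment token did not match the supported grammar."""


# ---------------------------------------------------------------------------
# domain types

@dataclass
class PeakRow:
    """One residue's observables from one spectrum.

    Floats default to NaN meaning *absent*; text fields default to ``""``.
    """

    residue_number: int
    residue_type: str = ""
    atom_f1: str = ""
    atom_f2: str = ""
    shift_f1: float = math.nan
    shift_f2: float = math.nan
    height: float = math.nan
    volume: float = math.nan
    linewidth_f1: float = math.nan
    linewidth_f2: float = math.nan
    merit: str = ""
    details: str = ""
    fit_method: str = ""
    status: str = STATUS_MEASURED

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(
                f"residue_number must be >= 1, got {self.residue_number}"
            )
        if self.status not in STATUSES:
            raise ValueError(f"invalid status {self.status!r}")

    @property
    def is_sidechain(self) -> bool:
        """NH2 sidechain entries carry atom names ending in 'a' or 'b'."""
        return bool(re.search(r"[ab]$", self.atom_f1)) or bool(
            re.search(r"[ab]$", self.atom_f2)
        )


class PeaklistTable:
    """Ordered collection of :class:`PeakRow` for one spectrum.

    Internally a :class:`pandas.DataFrame` with the canonical columns,
    sorted by residue number.  ``coordinate`` is the (z, y, x) label triple,
    unset until cube assembly.
    """

    def __init__(
        self,
        rows: Sequence[PeakRow] | pd.DataFrame = (),
        *,
        source_path: str = "",
        source_format: str = "",
        coordinate: tuple[str, str, str] | None = None,
    ):
        if isinstance(rows, pd.DataFrame):
            frame = rows.copy()
        else:
            frame = pd.DataFrame(
                [{f.name: getattr(r, f.name) for f in dc_fields(PeakRow)}
                 for r in rows],
            )
        for col in CANONICAL_COLUMNS:
            if col not in frame.columns:
                frame[col] = math.nan if col in _FLOAT_COLUMNS else ""
        extra = [c for c in frame.columns if c not in CANONICAL_COLUMNS]
        frame = frame[CANONICAL_COLUMNS + extra]
        frame["residue_number"] = frame["residue_number"].astype(int) \
            if len(frame) else frame["residue_number"].astype("int64")
        for col in _FLOAT_COLUMNS:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
        for col in _TEXT_COLUMNS:
            frame[col] = frame[col].fillna("").astype(str)
        frame = frame.sort_values(
            ["residue_number", "atom_f1"], kind="stable"
        ).reset_index(drop=True)
        self.frame = frame
        self.source_path = source_path
        self.source_format = source_format
        self.coordinate = coordinate

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[PeakRow]:
        for rec in self.frame[CANONICAL_COLUMNS].itertuples(index=False):
            yield PeakRow(**rec._asdict())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeaklistTable):
            return NotImplemented
        return tables_equal(self, other)

    @property
    def rows(self) -> list[PeakRow]:
        return list(self)

    @property
    def residue_numbers(self) -> np.ndarray:
        return self.frame["residue_number"].to_numpy()

    @property
    def derived_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in CANONICAL_COLUMNS]

    def backbone(self) -> "PeaklistTable":
        """Sub-table with sidechain rows removed."""
        mask = ~(
            self.frame["atom_f1"].str.contains(r"[ab]$", regex=True)
            | self.frame["atom_f2"].str.contains(r"[ab]$", regex=True)
        )
        return self.replace_frame(self.frame[mask].reset_index(drop=True))

    def replace_frame(self, frame: pd.DataFrame) -> "PeaklistTable":
        out = PeaklistTable(
            frame,
            source_path=self.source_path,
            source_format=self.source_format,
            coordinate=self.coordinate,
        )
        return out

    def copy(self) -> "PeaklistTable":
        return self.replace_frame(self.frame.copy())

    def validate(self) -> None:
        """Check table invariants; raise :class:`PeaklistError` on violation."""
        f = self.frame
        if (f["residue_number"] < 1).any():
            raise PeaklistError("residue numbers must be >= 1")
        bad_status = set(f["status"]) - set(STATUSES)
        if bad_status:
            raise PeaklistError(f"invalid status values: {sorted(bad_status)}")
        measured = f[f["status"] == STATUS_MEASURED]
        if measured[["shift_f1", "shift_f2"]].isna().any().any():
            raise PeaklistError("measured rows must have finite shifts")
        backbone = f[~(
            f["atom_f1"].str.contains(r"[ab]$", regex=True)
            | f["atom_f2"].str.contains(r"[ab]$", regex=True)
        )]
        dup = backbone["residue_number"].duplicated()
        if dup.any():
            dups = sorted(set(backbone.loc[dup, "residue_number"]))
            raise PeaklistError(
                f"duplicate backbone rows for residues {dups}"
            )


#: a table with derived observable columns appended; structurally identical
ResultTable = PeaklistTable


def tables_equal(a: PeaklistTable, b: PeaklistTable) -> bool:
    """Field-wise equality of all canonical + derived values (NaN == NaN)."""
    fa, fb = a.frame, b.frame
    if list(fa.columns) != list(fb.columns) or len(fa) != len(fb):
        return False
    for col in fa.columns:
        ca, cb = fa[col], fb[col]
        if ca.dtype.kind in "fc" or cb.dtype.kind in "fc":
            if not np.allclose(
                pd.to_numeric(ca, errors="coerce"),
                pd.to_numeric(cb, errors="coerce"),
                rtol=0, atol=0, equal_nan=True,
            ):
                return False
        else:
            if not (ca.astype(str) == cb.astype(str)).all():
                return False
    return True


# ---------------------------------------------------------------------------
# assignment grammar

_RE_1LETTER_PAIR = re.compile(
    r"^([A-Z])(\d+)([A-Za-z][A-Za-z0-9]*)-([A-Za-z][A-Za-z0-9]*)$"
)
_RE_3LETTER = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Za-z0-9]*)$")
_RE_1LETTER_SINGLE = re.compile(r"^([A-Z])(\d+)([A-Za-z][A-Za-z0-9]*)$")


def parse_assignment(token: str) -> tuple[int, str, str, str]:
    """Decompose an assignment token.

    Returns ``(residue_number, one_letter_type, atom_f1, atom_f2)``;
    ``atom_f2`` is ``""`` for single-atom tokens.

    >>> parse_assignment("T103N-H")
    (103, 'T', 'N', 'H')
    >>> parse_assignment("Gly45N")
    (45, 'G', 'N', '')
    """
    token = token.strip()
    m = _RE_1LETTER_PAIR.match(token)
    if m:
        code, num, a1, a2 = m.groups()
        if code not in AA1:
            raise AssignmentGrammarError(
                f"unknown one-letter residue code in {token!r}"
            )
        return int(num), code, a1, a2
    m = _RE_3LETTER.match(token)
    if m:
        code3, num, atom = m.groups()
        if code3 not in AA3_TO_1:
            raise AssignmentGrammarError(
                f"unknown three-letter residue code in {token!r}"
            )
        return int(num), AA3_TO_1[code3], atom, ""
    m = _RE_1LETTER_SINGLE.match(token)
    if m:
        code, num, atom = m.groups()
        if code not in AA1:
            raise AssignmentGrammarError(
                f"unknown one-letter residue code in {token!r}"
            )
        return int(num), code, atom, ""
    raise AssignmentGrammarError(
        f"assignment token {token!r} does not match the supported grammar"
    )


# ---------------------------------------------------------------------------
# format detection

_DIALECT_MARKERS: dict[str, list[str]] = {
    "nmrpipe": ["VARS", "X_PPM", "Y_PPM", "FORMAT"],
    "ccpnv2": ["Position F1", "Assign F1", "Position F2", "Assign F2"],
    "sparky": ["Assignment", "w1", "w2"],
    "nmrview": ["label dataset sw sf", "1H.L", "15N.L"],
}


def detect_format(text: str) -> str:
    """Identify the peaklist dialect from raw file content.

    Detection is marker-based on the header region.  Ansig files have no
    distinctive header and are never auto-detected; request them explicitly
    (they are rejected as unsupported either way).
    """
    if not text.strip():
        raise PeaklistError("cannot detect format of empty content")
    head_lines = text.splitlines()[:10]
    head = "\n".join(head_lines)
    first = text.lstrip().splitlines()[0]
    if any(ln.startswith("VARS") for ln in head_lines) and "X_PPM" in head:
        return "nmrpipe"
    if "Position F1" in head and "Assign F1" in head:
        return "ccpnv2"
    if first.startswith("label") and (".L" in head or ".P" in head):
        return "nmrview"
    if "Assignment" in head and "w1" in head:
        return "sparky"
    # nothing matched: name the closest candidate by marker overlap
    scores = {
        fmt: sum(marker in head for marker in markers)
        for fmt, markers in _DIALECT_MARKERS.items()
    }
    closest = max(scores, key=lambda k: (scores[k], k))
    raise UnrecognizedFormatError(closest)


# ---------------------------------------------------------------------------
# dialect parsers

def _to_float(token: str, lineno: int, what: str) -> float:
    token = token.strip()
    if token in ("", "-", "?", "None", "nan"):
        return math.nan
    try:
        return float(token)  # C-locale; scientific notation accepted
    except ValueError:
        raise PeaklistParseError(f"bad {what} value {token!r}", lineno)


def _parse_sparky(text: str, path: str) -> PeaklistTable:
    """Sparky list file: ``Assignment  w1  w2  [Data Height  [Volume]]``.

    ``w1`` is the heteronucleus shift, ``w2`` the 1H shift.
    """
    rows: list[PeakRow] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("Assignment"):
            continue
        toks = line.split()
        if len(toks) < 3:
            raise PeaklistParseError(
                f"expected at least 3 columns, got {len(toks)}", lineno
            )
        try:
            num, rtype, a1, a2 = parse_assignment(toks[0])
        except AssignmentGrammarError as exc:
            raise PeaklistParseError(str(exc), lineno) from exc
        rows.append(PeakRow(
            residue_number=num, residue_type=rtype, atom_f1=a1, atom_f2=a2,
            shift_f1=_to_float(toks[1], lineno, "w1"),
            shift_f2=_to_float(toks[2], lineno, "w2"),
            height=_to_float(toks[3], lineno, "height") if len(toks) > 3
            else math.nan,
            volume=_to_float(toks[4], lineno, "volume") if len(toks) > 4
            else math.nan,
        ))
    return PeaklistTable(rows, source_path=path, source_format="sparky")


_NMRPIPE_COLMAP = {
    # tab column -> (PeakRow field, note); X_PPM is the direct 1H dimension
    "Y_PPM": "shift_f1",
    "X_PPM": "shift_f2",
    "YW_HZ": "linewidth_f1",
    "XW_HZ": "linewidth_f2",
    "HEIGHT": "height",
    "VOL": "volume",
}


def _parse_nmrpipe(text: str, path: str) -> PeaklistTable:
    """NMRPipe ``.tab`` table with VARS/FORMAT header and an ASS column."""
    var_names: list[str] | None = None
    rows: list[PeakRow] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "REMARK", "DATA", "FORMAT")):
            continue
        if line.startswith("VARS"):
            var_names = line.split()[1:]
            continue
        if var_names is None:
            raise PeaklistParseError("data before VARS header", lineno)
        toks = line.split()
        if len(toks) != len(var_names):
            raise PeaklistParseError(
                f"expected {len(var_names)} columns, got {len(toks)}", lineno
            )
        rec = dict(zip(var_names, toks))
        if "ASS" not in rec:
            raise PeaklistParseError("no ASS column in VARS", lineno)
        try:
            num, rtype, a1, a2 = parse_assignment(rec["ASS"])
        except AssignmentGrammarError as exc:
            raise PeaklistParseError(str(exc), lineno) from exc
        kwargs: dict = {}
        for var, fld in _NMRPIPE_COLMAP.items():
            if var in rec:
                kwargs[fld] = _to_float(rec[var], lineno, var)
        rows.append(PeakRow(
            residue_number=num, residue_type=rtype, atom_f1=a1, atom_f2=a2,
            **kwargs,
        ))
    return PeaklistTable(rows, source_path=path, source_format="nmrpipe")


def _parse_ccpnv2(text: str, path: str) -> PeaklistTable:
    """CCPN Analysis v2 tabular export (comma-separated, named header).

    F1 is the heteronucleus dimension.  Merit/Details/Fit Method annotations
    are preserved verbatim.
    """
    buf = io.StringIO(text)
    try:
        frame = pd.read_csv(buf, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV
        raise PeaklistParseError(f"unreadable CCPN v2 table: {exc}")
    required = {"Position F1", "Position F2", "Assign F1"}
    missing = required - set(frame.columns)
    if missing:
        raise PeaklistParseError(
            f"CCPN v2 export missing columns: {sorted(missing)}"
        )
    rows: list[PeakRow] = []
    for i, rec in frame.iterrows():
        lineno = i + 2  # header is line 1
        try:
            num, rtype, a1, _ = parse_assignment(rec["Assign F1"])
        except AssignmentGrammarError as exc:
            raise PeaklistParseError(str(exc), lineno) from exc
        a2 = ""
        if rec.get("Assign F2", ""):
            num2, _, a2, _ = parse_assignment(rec["Assign F2"])
            if num2 != num:
                raise PeaklistParseError(
                    f"F1/F2 assignments disagree on residue number "
                    f"({num} vs {num2})", lineno,
                )
        rows.append(PeakRow(
            residue_number=num, residue_type=rtype, atom_f1=a1, atom_f2=a2,
            shift_f1=_to_float(rec["Position F1"], lineno, "Position F1"),
            shift_f2=_to_float(rec["Position F2"], lineno, "Position F2"),
            height=_to_float(rec.get("Height", ""), lineno, "Height"),
            volume=_to_float(rec.get("Volume", ""), lineno, "Volume"),
            linewidth_f1=_to_float(
                rec.get("Line Width F1 (Hz)", ""), lineno, "Line Width F1"),
            linewidth_f2=_to_float(
                rec.get("Line Width F2 (Hz)", ""), lineno, "Line Width F2"),
            merit=rec.get("Merit", ""),
            details=rec.get("Details", ""),
            fit_method=rec.get("Fit Method", ""),
        ))
    return PeaklistTable(rows, source_path=path, source_format="ccpnv2")


_RE_XPK_LABEL = re.compile(r"^\{(\d+)\.([A-Z])\.([A-Za-z0-9]+)\}$")


def _xpk_tokens(line: str) -> list[str]:
    """Tokenize an .xpk data line, keeping ``{...}`` groups intact."""
    return re.findall(r"\{[^}]*\}|\S+", line)


def _parse_nmrview(text: str, path: str) -> PeaklistTable:
    """NmrView ``.xpk``: header block then indexed rows with {n.T.atom} labels.

    Expected data columns (from the column-header line):
    ``1H.L 1H.P 15N.L 15N.P vol int``.
    """
    lines = text.splitlines()
    header_idx = None
    columns: list[str] = []
    for i, line in enumerate(lines):
        toks = line.split()
        if any(t.endswith(".L") for t in toks):
            header_idx = i
            columns = toks
            break
    if header_idx is None:
        raise PeaklistParseError("no .xpk column header line found")

    def col(name: str) -> int | None:
        return columns.index(name) if name in columns else None

    i_hl, i_hp = col("1H.L"), col("1H.P")
    i_nl, i_np = col("15N.L"), col("15N.P")
    i_vol, i_int = col("vol"), col("int")
    if None in (i_hl, i_hp, i_nl, i_np):
        raise PeaklistParseError(
            "xpk header must contain 1H.L 1H.P 15N.L 15N.P"
        )
    rows: list[PeakRow] = []
    for lineno, raw in enumerate(
        lines[header_idx + 1:], start=header_idx + 2
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = _xpk_tokens(line)[1:]  # leading peak index dropped
        if len(toks) < len(columns):
            raise PeaklistParseError(
                f"expected {len(columns)} columns, got {len(toks)}", lineno
            )
        m_h = _RE_XPK_LABEL.match(toks[i_hl])
        m_n = _RE_XPK_LABEL.match(toks[i_nl])
        if not (m_h and m_n):
            raise PeaklistParseError(
                f"bad xpk label {toks[i_hl]!r}/{toks[i_nl]!r}", lineno
            )
        num = int(m_h.group(1))
        if int(m_n.group(1)) != num:
            raise PeaklistParseError(
                "1H and 15N labels disagree on residue number", lineno
            )
        rtype = m_h.group(2)
        if rtype not in AA1:
            raise PeaklistParseError(
                f"unknown residue code {rtype!r}", lineno
            )
        rows.append(PeakRow(
            residue_number=num, residue_type=rtype,
            atom_f1=m_n.group(3), atom_f2=m_h.group(3),
            shift_f1=_to_float(toks[i_np], lineno, "15N.P"),
            shift_f2=_to_float(toks[i_hp], lineno, "1H.P"),
            height=(_to_float(toks[i_int], lineno, "int")
                    if i_int is not None else math.nan),
            volume=(_to_float(toks[i_vol], lineno, "vol")
                    if i_vol is not None else math.nan),
        ))
    return PeaklistTable(rows, source_path=path, source_format="nmrview")


_PARSERS = {
    "sparky": _parse_sparky,
    "nmrpipe": _parse_nmrpipe,
    "ccpnv2": _parse_ccpnv2,
    "nmrview": _parse_nmrview,
}


def parse_peaklist(
    path: str | Path, fmt: Optional[str] = None
) -> PeaklistTable:
    """Parse a peaklist file into a :class:`PeaklistTable`.

    Parameters
    ----------
    path
        Peaklist file location.
    fmt
        Dialect identifier; auto-detected from content when omitted.
    """
    path = Path(path)
    text = path.read_text()
    if fmt is None:
        if not text.strip():
            logger.warning("empty peaklist file %s", path)
            return PeaklistTable([], source_path=str(path), source_format="")
        fmt = detect_format(text)
    if fmt == "ansig":
        raise UnsupportedDialectError(
            "unsupported dialect: the Ansig fixed-width format is not parsed"
        )
    if fmt not in _PARSERS:
        raise PeaklistError(f"unknown format identifier {fmt!r}")
    if not text.strip():
        logger.warning("empty peaklist file %s", path)
        return PeaklistTable([], source_path=str(path), source_format=fmt)
    table = _PARSERS[fmt](text, str(path))
    if len(table) == 0:
        logger.warning("peaklist %s parsed to zero rows", path)
    return table


def parse_peaklist_text(
    text: str, fmt: Optional[str] = None, path: str = "<memory>"
) -> PeaklistTable:
    """Like :func:`parse_peaklist` but from in-memory text."""
    if fmt is None:
        fmt = detect_format(text)
    if fmt == "ansig":
        raise UnsupportedDialectError(
            "unsupported dialect: the Ansig fixed-width format is not parsed"
        )
    return _PARSERS[fmt](text, path)


# ---------------------------------------------------------------------------
# canonical CSV

def write_canonical_csv(table: PeaklistTable, path: str | Path) -> None:
    """Write the canonical comma-separated form (RFC-4180 quoting).

    Header row uses the fixed canonical column order; derived columns
    (CSP, ratios, ΔPRE, ...) follow the canonical ones.  Re-reading with
    :func:`read_canonical_csv` reproduces every field value.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, index=False)


def read_canonical_csv(path: str | Path) -> PeaklistTable:
    """Read a canonical CSV written by :func:`write_canonical_csv`."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in frame.columns:
        if col in _TEXT_COLUMNS:
            continue
        if col == "residue_number":
            frame[col] = frame[col].astype(int)
        else:
            # float() round-trips shortest-repr decimals exactly
            frame[col] = frame[col].map(
                lambda s: math.nan if s == "" else float(s)
            )
    return PeaklistTable(frame, source_path=str(path), source_format="canonical")
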