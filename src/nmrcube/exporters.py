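"""Molecular-viewer attribute files and the hierarchical results tree.

Per-residue derived values can be painted onto a 3D structure in UCSF
Chimera via its "Define attribute" text format; :func:`write_chimera_attributes`
emits that format bit-exactly.  An exporter registry keyed by viewer name
leaves room for other dialects; only the Chimera writer ships.

All run output lands in a folder hierarchy ``output_root/<z>/<y>/<analysis>/``
mirroring the cube coordinates, with a ``manifest.csv`` listing every file.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


class ExportError(Exception):
    pass


_ATTR_NAME_RE = re.compile(r"^[a-z][A-Za-z0-9_]*$")


def _format_value(value: float) -> str:
    """Shortest clean decimal at <= 6 significant digits."""
    text = f"{float(value):.6g}"
    return text


def write_chimera_attributes(
    values: pd.Series, attribute: str, path: str | Path
) -> Path:
    """Write a UCSF Chimera residue-attribute file.

    ``values`` is a per-residue series (index = residue number); NaN entries
    are omitted.  The attribute name must start lowercase and contain only
    word characters, or the viewer rejects the file.
    """
    if not _ATTR_NAME_RE.match(attribute):
        raise ExportError(
            f"invalid attribute name {attribute!r} "
            "(must match ^[a-z][A-Za-z0-9_]*$)"
        )
    values = values.dropna()
    if values.empty:
        raise ExportError("nothing to export: attribute column is empty")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"attribute: {attribute}",
        "match mode: 1-to-1",
        "recipient: residues",
    ]
    for num, val in values.items():
        lines.append(f"\t:{int(num)}\t{_format_value(val)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def parse_chimera_attributes(path: str | Path) -> tuple[str, pd.Series]:
    """Read back a Chimera attribute file (for round-trip checks)."""
    name = ""
    nums: list[int] = []
    vals: list[float] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("attribute:"):
            name = line.split(":", 1)[1].strip()
        elif line.startswith("\t:"):
            sel, val = line.strip().split("\t")
            nums.append(int(sel.lstrip(":")))
            vals.append(float(val))
    return name, pd.Series(vals, index=nums, name=name)


#: registry keyed by target viewer; only chimera ships
EXPORTER_REGISTRY = {"chimera": write_chimera_attributes}


def register_exporter(viewer: str, func) -> None:
    EXPORTER_REGISTRY[viewer] = func


# ---------------------------------------------------------------------------
# output tree

def prepare_output_root(root: str | Path, overwrite: bool = False) -> Path:
    """Create (or refuse to reuse) the output root directory."""
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        if not overwrite:
            raise ExportError(
                f"output root {root} is not empty; pass overwrite to reuse"
            )
    root.mkdir(parents=True, exist_ok=True)
    return root


def analysis_dir(root: Path, z: str, y: str, analysis: str) -> Path:
    """``output_root/<z>/<y>/<analysis>/`` -- coordinates outermost first."""
    d = Path(root) / z / y / analysis
    d.mkdir(parents=True, exist_ok=True)
    return d


class Manifest:
    """Accumulates (path, coordinate, type) records for every written file."""

    def __init__(self, root: Path):
        self.root = Path(root)
        self.records: list[dict] = []

    def add(self, path: str | Path, coordinate: str, kind: str) -> None:
        rel = Path(path).relative_to(self.root)
        self.records.append(
            {"path": str(rel), "coordinate": coordinate, "type": kind}
        )

    def write(self) -> Path:
        frame = pd.DataFrame(
            self.records, columns=["path", "coordinate", "type"]
        ).sort_values(["path"]).reset_index(drop=True)
        out = self.root / "manifest.csv"
        frame.to_csv(out, index=False)
        return out

    def audit(self) -> bool:
        """True when every manifest row exists on disk and vice versa."""
        on_disk = {
            str(p.relative_to(self.root))
            for p in self.root.rglob("*")
            if p.is_file() and p.name != "manifest.csv"
        }
        listed = {r["path"] for r in self.records}
        missing = listed - on_disk
        unlisted = on_disk - listed
        if missing:
            logger.error("manifest rows without files: %s", sorted(missing))
        if unlisted:
            logger.error("files not in manifest: %s", sorted(unlisted))
        return not missing and not unlisted
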