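"""Run-configuration file: schema, validation, normalization.

A single JSON file drives an entire calculation: the three axis label
lists, the coordinate → peaklist-file manifest, curation and observable
options, which analyses to run, the plot templates and the exports.
Unknown keys only warn; schema violations are reported all at once.  The
normalized configuration is saved back into the output tree so a run can
be reloaded and repeated later.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError

logger = logging.getLogger(__name__)

COORD_SEP = "|"   # manifest keys are "z|y|x"


class ConfigError(Exception):
    pass


class _Model(BaseModel):
    model_config = ConfigDict(extra="allow", validate_assignment=True)

    def warn_extras(self, where: str) -> None:
        for key in (self.model_extra or {}):
            logger.warning("unknown configuration key %r in %s", key, where)


class AxesConfig(_Model):
    x: list[str] = Field(min_length=1)
    y: list[str] = Field(default_factory=lambda: ["y0"], min_length=1)
    z: list[str] = Field(default_factory=lambda: ["z0"], min_length=1)


class CurationConfig(_Model):
    fill_policy: Literal["carry_last", "blank"] = "carry_last"
    sequence: Optional[str] = None      # FASTA path or "first:last"
    keep_sidechains: bool = True


class ObservablesConfig(_Model):
    alpha_default: float = Field(0.14, gt=0)
    alpha_map: dict[str, float] = Field(default_factory=lambda: {"G": 0.2})
    ratio_kind: Literal["height", "volume"] = "height"
    smoothing_sigma: float = Field(3.0, gt=0)
    smoothing_halfwidth: Optional[int] = Field(None, ge=1)
    significance_threshold: Optional[float] = None
    dpre_sign: Literal[1, -1] = 1
    shift_normalize_residue: Optional[int] = None


class AnalysesConfig(_Model):
    csp: bool = True
    ratios: bool = True
    dpre: bool = False
    fitting: bool = False


class FittingConfig(_Model):
    model: Literal["hill", "one_site_depletion"] = "hill"
    protein_conc: Optional[float] = Field(None, gt=0)
    min_points: int = Field(4, ge=2)
    response_floor: Optional[float] = Field(None, ge=0)


class DpreConfig(_Model):
    #: y-label -> path of the predicted random-coil profile table
    predicted_profiles: dict[str, str] = Field(default_factory=dict)


class ExportConfig(_Model):
    chimera_attributes: list[str] = Field(default_factory=list)


class RunConfig(_Model):
    axes: AxesConfig
    peaklists: dict[str, str]
    curation: CurationConfig = Field(default_factory=CurationConfig)
    observables: ObservablesConfig = Field(default_factory=ObservablesConfig)
    analyses: AnalysesConfig = Field(default_factory=AnalysesConfig)
    fitting: FittingConfig = Field(default_factory=FittingConfig)
    dpre: DpreConfig = Field(default_factory=DpreConfig)
    plots: list[str] = Field(default_factory=lambda: ["bar_extended"])
    export: ExportConfig = Field(default_factory=ExportConfig)
    base_dir: str = "."   # directory paths in the manifest are relative to

    def coordinate_paths(self) -> dict[tuple[str, str, str], Path]:
        base = Path(self.base_dir)
        out = {}
        for key, rel in self.peaklists.items():
            parts = key.split(COORD_SEP)
            if len(parts) != 3:
                raise ConfigError(
                    f"peaklist key {key!r} is not 'z{COORD_SEP}y"
                    f"{COORD_SEP}x'"
                )
            out[tuple(parts)] = base / rel
        return out

    @property
    def x_is_numeric(self) -> bool:
        try:
            vals = [float(v) for v in self.axes.x]
        except ValueError:
            return False
        return all(b > a for a, b in zip(vals, vals[1:]))


def _semantic_errors(cfg: RunConfig) -> list[str]:
    errors: list[str] = []
    expected = {
        (z, y, x)
        for z in cfg.axes.z for y in cfg.axes.y for x in cfg.axes.x
    }
    try:
        got = set(cfg.coordinate_paths())
    except ConfigError as exc:
        return [str(exc)]
    missing = expected - got
    extra = got - expected
    if missing:
        errors.append(f"peaklists missing for coordinates "
                      f"{sorted(missing)[:5]}")
    if extra:
        errors.append(f"peaklists given for unknown coordinates "
                      f"{sorted(extra)[:5]}")
    if cfg.analyses.fitting and not cfg.x_is_numeric:
        errors.append(
            "fitting of continuous data requires numeric, strictly "
            f"increasing x-axis labels; got {cfg.axes.x}"
        )
    if cfg.analyses.dpre and len(cfg.axes.z) != 2:
        errors.append(
            "ΔPRE analysis runs along z and needs exactly the "
            f"(diamagnetic, paramagnetic) pair; |z| = {len(cfg.axes.z)}"
        )
    if cfg.fitting.model == "one_site_depletion" \
            and cfg.analyses.fitting and cfg.fitting.protein_conc is None:
        errors.append("one_site_depletion fitting requires protein_conc")
    from .plotting import TEMPLATES
    for tpl in cfg.plots:
        if tpl not in TEMPLATES:
            errors.append(f"unknown plot template {tpl!r}")
    return errors


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run-configuration JSON file.

    All schema and semantic problems are collected and reported in a single
    :class:`ConfigError`; unknown keys merely warn.  Relative peaklist
    paths are resolved against the configuration file's directory.
    """
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"configuration file {path} does not exist")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"configuration is not valid JSON: {exc}")
    raw.setdefault("base_dir", str(path.parent))
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(
            "invalid configuration:\n  " + "\n  ".join(lines)
        ) from exc
    cfg.warn_extras("top level")
    for name in ("axes", "curation", "observables", "analyses",
                 "fitting", "dpre", "export"):
        getattr(cfg, name).warn_extras(name)
    errors = _semantic_errors(cfg)
    if errors:
        raise ConfigError(
            "invalid configuration:\n  " + "\n  ".join(errors)
        )
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    """Write the normalized (default-populated) configuration back out."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = cfg.model_dump(exclude={"base_dir"})
    path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    return path
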