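"""Publication-style figure templates for per-residue NMR parameters.

Eight templates: three bar plots (extended, compacted, vertical), two
scatter plots (shift map, peak trajectory), a heat map, the smoothed-ΔPRE
profile overlay, and a per-residue evolution grid.

Colour semantics throughout: black = measured, red = missing (peak
disappeared; carried value), grey = unassigned; prolines are marked with
the character "P"; an optional significance threshold is drawn as a red
line.

Every figure is written together with a *sidecar* CSV containing exactly
the plotted values; tests assert on sidecars and on figure-file existence,
never on pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .comparative import ComparativeTable  # noqa: E402
from .peaklist_io import (  # noqa: E402
    STATUS_MEASURED,
    STATUS_MISSING,
    STATUS_UNASSIGNED,
    ResultTable,
)

logger = logging.getLogger(__name__)

TEMPLATES = (
    "bar_extended",
    "bar_compacted",
    "bar_vertical",
    "scatter_shift_map",
    "scatter_trajectory",
    "heat_map",
    "dpre_profile",
    "residue_evolution",
)


class PlotError(Exception):
    pass


@dataclass
class PlotConfig:
    template: str = "bar_extended"
    value_column: str = "csp"
    colour_measured: str = "black"
    colour_missing: str = "red"
    colour_unassigned: str = "0.6"
    threshold: float | None = None
    threshold_colour: str = "red"
    file_format: str = "pdf"
    dpi: int = 300
    figsize: tuple[float, float] | None = None
    max_subplots: int = 100

    def __post_init__(self):
        if self.template not in TEMPLATES:
            raise PlotError(
                f"unknown template {self.template!r}; "
                f"choose one of {TEMPLATES}"
            )
        if self.dpi <= 0:
            raise PlotError("dpi must be > 0")
        if self.file_format not in ("pdf", "png", "svg"):
            raise PlotError(f"unsupported figure format {self.file_format!r}")


def _require_columns(frame: pd.DataFrame, cols: Sequence[str]) -> None:
    for col in cols:
        if col not in frame.columns:
            raise PlotError(f"required column {col!r} is missing")


def _status_colours(status: pd.Series, cfg: PlotConfig) -> list[str]:
    lut = {
        STATUS_MEASURED: cfg.colour_measured,
        STATUS_MISSING: cfg.colour_missing,
        STATUS_UNASSIGNED: cfg.colour_unassigned,
    }
    return [lut.get(s, cfg.colour_measured) for s in status]


# ---------------------------------------------------------------------------
# per-template sidecar + drawing

def _bar_sidecar(table: ResultTable, cfg: PlotConfig) -> pd.DataFrame:
    _require_columns(table.frame, [cfg.value_column])
    out = table.frame[
        ["residue_number", "residue_type", "status", cfg.value_column]
    ].copy()
    return out


def _draw_bars(ax, side: pd.DataFrame, cfg: PlotConfig,
               vertical: bool = False, shade_unassigned: bool = False):
    x = side["residue_number"].to_numpy()
    y = side[cfg.value_column].to_numpy(dtype=float)
    colours = _status_colours(side["status"], cfg)
    y_plot = np.nan_to_num(y, nan=0.0)
    if vertical:
        ax.barh(x, y_plot, color=colours)
        ax.set_ylabel("residue")
        ax.set_xlabel(cfg.value_column)
        if cfg.threshold is not None:
            ax.axvline(cfg.threshold, color=cfg.threshold_colour, lw=0.8)
    else:
        ax.bar(x, y_plot, color=colours)
        ax.set_xlabel("residue")
        ax.set_ylabel(cfg.value_column)
        if cfg.threshold is not None:
            ax.axhline(cfg.threshold, color=cfg.threshold_colour, lw=0.8)
    if shade_unassigned and not vertical:
        for xi, st in zip(x, side["status"]):
            if st == STATUS_UNASSIGNED:
                ax.axvspan(xi - 0.5, xi + 0.5,
                           color=cfg.colour_unassigned, alpha=0.3, lw=0)
    # prolines labelled "P"
    pro = side[side["residue_type"] == "P"]
    for _, row in pro.iterrows():
        if vertical:
            ax.text(0, row["residue_number"], "P", fontsize=6, va="center")
        else:
            ax.text(row["residue_number"], 0, "P", fontsize=6, ha="center")


def _render_bar(table: ResultTable, cfg: PlotConfig, path: Path,
                vertical=False, shade=False) -> pd.DataFrame:
    side = _bar_sidecar(table, cfg)
    figsize = cfg.figsize or ((4, 8) if vertical else (10, 3))
    fig, ax = plt.subplots(figsize=figsize)
    _draw_bars(ax, side, cfg, vertical=vertical, shade_unassigned=shade)
    fig.savefig(path, dpi=cfg.dpi)
    plt.close(fig)
    return side


def _render_shift_map(table: ResultTable, cfg: PlotConfig,
                      path: Path) -> pd.DataFrame:
    _require_columns(table.frame, ["delta_h", "delta_x"])
    side = table.frame[
        ["residue_number", "status", "delta_h", "delta_x"]
    ].copy()
    fig, ax = plt.subplots(figsize=cfg.figsize or (5, 5))
    ax.scatter(side["delta_h"], side["delta_x"],
               c=_status_colours(side["status"], cfg), s=12)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel("Δδ 1H (ppm)")
    ax.set_ylabel("Δδ 15N (ppm)")
    fig.savefig(path, dpi=cfg.dpi)
    plt.close(fig)
    return side


def _render_trajectory(tables: Sequence[ResultTable], labels: Sequence[str],
                       cfg: PlotConfig, path: Path) -> pd.DataFrame:
    records = []
    for lbl, t in zip(labels, tables):
        _require_columns(t.frame, ["shift_f1", "shift_f2"])
        sub = t.frame[["residue_number", "shift_f1", "shift_f2",
                       "status"]].copy()
        sub.insert(0, "point", lbl)
        records.append(sub)
    side = pd.concat(records, ignore_index=True)
    fig, ax = plt.subplots(figsize=cfg.figsize or (6, 6))
    for num, grp in side.groupby("residue_number"):
        ax.plot(grp["shift_f2"], grp["shift_f1"], "-o", ms=2, lw=0.6)
    ax.invert_xaxis()
    ax.invert_yaxis()
    ax.set_xlabel("δ 1H (ppm)")
    ax.set_ylabel("δ 15N (ppm)")
    fig.savefig(path, dpi=cfg.dpi)
    plt.close(fig)
    return side


def _render_heat_map(table: ComparativeTable, cfg: PlotConfig,
                     path: Path) -> pd.DataFrame:
    matrix = table.matrix
    fig, ax = plt.subplots(figsize=cfg.figsize or (6, 4))
    im = ax.imshow(
        matrix.T.to_numpy(dtype=float), aspect="auto",
        interpolation="nearest",
        extent=(matrix.index.min() - 0.5, matrix.index.max() + 0.5,
                len(matrix.columns) - 0.5, -0.5),
    )
    ax.set_yticks(range(len(matrix.columns)), labels=matrix.columns)
    ax.set_xlabel("residue")
    fig.colorbar(im, ax=ax, label=table.parameter)
    fig.savefig(path, dpi=cfg.dpi)
    plt.close(fig)
    side = matrix.reset_index()
    return side


def _render_dpre_profile(table: ResultTable, predicted: pd.Series,
                         cfg: PlotConfig, path: Path) -> pd.DataFrame:
    _require_columns(table.frame, ["height_ratio", "dpre", "smoothed_dpre"])
    frame = table.frame.set_index("residue_number")
    side = pd.DataFrame({
        "residue_number": frame.index,
        "observed_ratio": frame["height_ratio"].to_numpy(),
        "predicted_ratio": predicted.reindex(frame.index).to_numpy(),
        "dpre": frame["dpre"].to_numpy(),
        "smoothed_dpre": frame["smoothed_dpre"].to_numpy(),
    })
    fig, (ax1, ax2) = plt.subplots(
        2, 1, sharex=True, figsize=cfg.figsize or (8, 5))
    ax1.plot(side["residue_number"], side["predicted_ratio"],
             color="0.5", lw=1, label="random-coil prediction")
    ax1.plot(side["residue_number"], side["observed_ratio"],
             color="black", lw=1, label="observed I_para/I_dia")
    ax1.set_ylabel("intensity ratio")
    ax1.legend(fontsize=7)
    ax2.bar(side["residue_number"], np.nan_to_num(side["dpre"], nan=0.0),
            color="0.75", label="ΔPRE")
    ax2.plot(side["residue_number"], side["smoothed_dpre"],
             color="red", lw=1.2, label="smoothed ΔPRE")
    ax2.set_xlabel("residue")
    ax2.set_ylabel("ΔPRE")
    ax2.legend(fontsize=7)
    fig.savefig(path, dpi=cfg.dpi)
    plt.close(fig)
    return side


def _render_residue_evolution(
    tables: Sequence[ResultTable], x_values: Sequence[float],
    cfg: PlotConfig, path: Path, curves: pd.DataFrame | None = None,
) -> pd.DataFrame:
    matrix = {}
    for x, t in zip(x_values, tables):
        _require_columns(t.frame, [cfg.value_column])
        matrix[x] = t.frame.set_index("residue_number")[cfg.value_column]
    wide = pd.DataFrame(matrix)
    wide.index.name = "residue_number"
    residues = [n for n in wide.index
                if wide.loc[n].notna().any()][: cfg.max_subplots]
    n = max(len(residues), 1)
    ncols = min(10, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=cfg.figsize or (1.6 * ncols, 1.4 * nrows),
        squeeze=False, sharex=True,
    )
    for ax in axes.flat:
        ax.set_visible(False)
    for ax, num in zip(axes.flat, residues):
        ax.set_visible(True)
        ax.plot(wide.columns, wide.loc[num], "ko", ms=2)
        if curves is not None and num in curves.columns:
            ax.plot(curves.index, curves[num], "r-", lw=0.7)
        ax.set_title(str(num), fontsize=6)
        ax.tick_params(labelsize=5)
    fig.savefig(path, dpi=cfg.dpi)
    plt.close(fig)
    return wide.reset_index()


# ---------------------------------------------------------------------------
# dispatcher

def render(
    template: str,
    data,
    config: PlotConfig | None = None,
    out_path: str | Path = "figure.pdf",
    **extra,
) -> tuple[Path, Path]:
    """Render one template and its sidecar CSV.

    ``data`` depends on the template: a :class:`ResultTable` for the bar
    plots, the shift map and the ΔPRE profile (the latter also needs
    ``predicted=`` profile); a list of tables plus ``labels=``/``x_values=``
    for trajectory and evolution; a :class:`ComparativeTable` for the heat
    map.  Returns ``(figure_path, sidecar_path)``.
    """
    config = config or PlotConfig(template=template)
    if config.template != template:
        config = PlotConfig(**{**config.__dict__, "template": template})
    out_path = Path(out_path).with_suffix("." + config.file_format)
    out_path.parent.mkdir(parents=True, exist_ok=True)

    def empty(obj) -> bool:
        if obj is None:
            return True
        if isinstance(obj, ComparativeTable):
            return obj.matrix.empty
        if isinstance(obj, (list, tuple)):
            return len(obj) == 0 or all(len(t) == 0 for t in obj)
        return len(obj) == 0

    if empty(data):
        raise PlotError("nothing to plot")

    if template == "bar_extended":
        side = _render_bar(data, config, out_path)
    elif template == "bar_compacted":
        side = _render_bar(data, config, out_path, shade=True)
    elif template == "bar_vertical":
        side = _render_bar(data, config, out_path, vertical=True)
    elif template == "scatter_shift_map":
        side = _render_shift_map(data, config, out_path)
    elif template == "scatter_trajectory":
        side = _render_trajectory(data, extra["labels"], config, out_path)
    elif template == "heat_map":
        side = _render_heat_map(data, config, out_path)
    elif template == "dpre_profile":
        side = _render_dpre_profile(
            data, extra["predicted"], config, out_path)
    elif template == "residue_evolution":
        side = _render_residue_evolution(
            data, extra["x_values"], config, out_path,
            curves=extra.get("curves"),
        )
    else:  # pragma: no cover - guarded by PlotConfig
        raise PlotError(f"unknown template {template!r}")

    sidecar_path = out_path.with_suffix(".csv")
    side.to_csv(sidecar_path, index=False)
    return out_path, sidecar_path


def render_all(requests: Sequence[dict]) -> list[tuple[Path, Path]]:
    """Render a batch of figures; per-figure failures are logged, not raised.

    Each request is the keyword dict for one :func:`render` call.  Returns
    the (figure, sidecar) paths of the successful renders; the produced
    count is logged.
    """
    produced: list[tuple[Path, Path]] = []
    if not requests:
        logger.info("no plot templates selected; zero figures produced")
        return produced
    for req in requests:
        try:
            produced.append(render(**req))
        except Exception as exc:
            logger.error("figure %s failed: %s",
                         req.get("out_path", "?"), exc)
    logger.info("rendered %d/%d figures", len(produced), len(requests))
    return produced
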