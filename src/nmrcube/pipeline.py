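"""End-to-end run orchestration.

``run()`` executes the full deterministic pipeline described by a
:class:`~nmrcube.config.RunConfig`:

    parse → sidechain split → cube → curation (scan + pad along x)
    → per-series observables → fitting → ΔPRE → comparative stacking
    → plots → exports → manifest

Warnings never abort; a stage error aborts the run but partial output and
the manifest of what was completed are preserved.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .comparative import ComparativeTable, compare_across, stack
from .config import RunConfig, save_config
from .cube import AXES, AxisSpec, Cube, Series, axis_policy_check, \
    build_cube, enumerate_series
from .curation import pad_tables, parse_sequence_spec, scan_series, \
    tag_sidechains
from .exporters import Manifest, analysis_dir, prepare_output_root, \
    write_chimera_attributes
from .fitting import FitConfig, fit_series
from .observables import ObservableConfig, compute_observables, \
    read_predicted_profile
from .peaklist_io import parse_peaklist, write_canonical_csv
from .plotting import PlotConfig, render_all

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    pass


@dataclasses.dataclass
class RunSummary:
    peaklists_read: int = 0
    sidechain_rows: int = 0
    residues_missing: int = 0
    residues_unassigned: int = 0
    series_analysed: int = 0
    residues_fit: int = 0
    figures_written: int = 0
    files_written: int = 0
    manifest_path: str = ""

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _observable_config(cfg: RunConfig) -> ObservableConfig:
    o = cfg.observables
    return ObservableConfig(
        alpha_default=o.alpha_default,
        alpha_map=dict(o.alpha_map),
        ratio_kind=o.ratio_kind,
        smoothing_sigma=o.smoothing_sigma,
        smoothing_halfwidth=o.smoothing_halfwidth,
        significance_threshold=o.significance_threshold,
        dpre_sign=o.dpre_sign,
    )


def _series_key(series: Series) -> tuple:
    return tuple(sorted(series.fixed.items()))


def _ensure_uniform(series: Series, sequence=None) -> Series:
    """Pad a (y/z) series whose tables do not share a residue index yet."""
    first = series.tables[0].residue_numbers
    if all(np.array_equal(first, t.residue_numbers)
           for t in series.tables[1:]):
        return series
    return pad_tables(series, scan_series(series, sequence))


def run(cfg: RunConfig, output_root: str | Path,
        overwrite: bool = False) -> RunSummary:
    """Execute the configured pipeline; returns the run summary."""
    root = prepare_output_root(output_root, overwrite)
    manifest = Manifest(root)
    summary = RunSummary()
    try:
        _run_stages(cfg, root, manifest, summary)
    finally:
        mpath = manifest.write()
        summary.manifest_path = str(mpath)
        summary.files_written = len(manifest.records)
        logger.info(
            "run summary: %d peaklists, %d series, %d figures, %d files",
            summary.peaklists_read, summary.series_analysed,
            summary.figures_written, summary.files_written,
        )
    return summary


def _run_stages(cfg: RunConfig, root: Path, manifest: Manifest,
                summary: RunSummary) -> None:
    norm = save_config(cfg, root / "run_config.normalized.json")
    manifest.add(norm, "-", "config")

    # ---- parse + sidechains ----------------------------------------------
    tables = {}
    sidechains = {}
    for coord, path in sorted(cfg.coordinate_paths().items()):
        table = parse_peaklist(path)
        backbone, side = tag_sidechains(
            table, keep=cfg.curation.keep_sidechains)
        tables[coord] = backbone
        if side is not None and len(side):
            sidechains[coord] = side
            summary.sidechain_rows += len(side)
        summary.peaklists_read += 1

    axes = {a: AxisSpec(a, tuple(getattr(cfg.axes, a))) for a in AXES}
    cube = build_cube(tables, axes)

    requested = []
    if cfg.analyses.csp or cfg.analyses.ratios:
        requested.append(("csp" if cfg.analyses.csp else "height_ratio",
                          "x"))
    if cfg.analyses.dpre:
        requested.append(("dpre", "z"))
    if cfg.analyses.fitting:
        requested.append(("fitting", "x"))
    axis_policy_check(cube, requested)

    sequence = None
    if cfg.curation.sequence:
        seq_spec = cfg.curation.sequence
        if Path(cfg.base_dir, seq_spec).is_file():
            seq_spec = Path(cfg.base_dir, seq_spec)
        sequence = parse_sequence_spec(seq_spec)

    # ---- curation along x -------------------------------------------------
    padded_cells = {}
    for series in enumerate_series(cube, "x"):
        scan = scan_series(series, sequence)
        padded = pad_tables(series, scan, cfg.curation.fill_policy)
        last = padded.labels[-1]
        counts = scan.counts(last)
        summary.residues_missing += counts["missing"]
        summary.residues_unassigned += counts["unassigned"]
        for lbl, table in zip(padded.labels, padded.tables):
            padded_cells[(series.fixed["z"], series.fixed["y"], lbl)] = table
    cube = Cube(axes, padded_cells)

    obs_cfg = _observable_config(cfg)
    plot_requests: list[dict] = []
    threshold = cfg.observables.significance_threshold

    # ---- per-series observables + fitting along x -------------------------
    x_numeric = cube.axes["x"].numeric_values
    run_x = (cfg.analyses.csp or cfg.analyses.ratios) and len(axes["x"]) > 1
    if (cfg.analyses.csp or cfg.analyses.ratios) and len(axes["x"]) == 1:
        logger.info("x axis has a single point; x-series analyses skipped")
    if run_x:
        for series in enumerate_series(cube, "x"):
            z, y = series.fixed["z"], series.fixed["y"]
            results = compute_observables(series, obs_cfg)
            summary.series_analysed += 1
            adir = analysis_dir(root, z, y, "along_x")
            for lbl, table in zip(series.labels, results):
                out = adir / f"peaklist_{lbl}.csv"
                write_canonical_csv(table, out)
                manifest.add(out, f"{z}|{y}|{lbl}", "result_table")
            curves = None
            if cfg.analyses.fitting and x_numeric is not None \
                    and len(series) >= cfg.fitting.min_points:
                fit_cfg = FitConfig(
                    model=cfg.fitting.model,
                    protein_conc=cfg.fitting.protein_conc,
                    response_floor=cfg.fitting.response_floor,
                    min_points=cfg.fitting.min_points,
                )
                fits, fits_table, curves = fit_series(
                    results, x_numeric, series.labels, fit_cfg)
                fpath = analysis_dir(root, z, y, "fits") / "fits.csv"
                fits_table.to_csv(fpath, index=False)
                manifest.add(fpath, f"{z}|{y}|-", "fits")
                summary.residues_fit += sum(f.converged for f in fits)
            pdir = analysis_dir(root, z, y, "plots")
            for tpl in cfg.plots:
                if tpl in ("bar_extended", "bar_compacted", "bar_vertical",
                           "scatter_shift_map"):
                    plot_requests.append(dict(
                        template=tpl, data=results[-1],
                        config=PlotConfig(template=tpl,
                                          threshold=threshold),
                        out_path=pdir / tpl,
                    ))
                elif tpl == "scatter_trajectory":
                    plot_requests.append(dict(
                        template=tpl, data=results,
                        labels=series.labels,
                        config=PlotConfig(template=tpl),
                        out_path=pdir / tpl,
                    ))
                elif tpl == "residue_evolution":
                    xs = x_numeric if x_numeric is not None \
                        else tuple(range(len(series)))
                    plot_requests.append(dict(
                        template=tpl, data=results, x_values=xs,
                        curves=curves,
                        config=PlotConfig(template=tpl),
                        out_path=pdir / tpl,
                    ))
            # exports from the final series point
            for column in cfg.export.chimera_attributes:
                frame = results[-1].frame
                if column not in frame.columns:
                    logger.error("export column %r missing", column)
                    continue
                values = frame.set_index("residue_number")[column]
                apath = analysis_dir(root, z, y, "attributes") \
                    / f"{column}.attr"
                write_chimera_attributes(values, column, apath)
                manifest.add(apath, f"{z}|{y}|{series.labels[-1]}",
                             "chimera_attributes")

    # ---- ΔPRE along z ------------------------------------------------------
    dpre_sources: dict[str, object] = {}
    if cfg.analyses.dpre:
        for series in enumerate_series(cube, "z"):
            y = series.fixed["y"]
            x = series.fixed["x"]
            prof_path = cfg.dpre.predicted_profiles.get(y)
            if prof_path is None:
                logger.error("no predicted PRE profile for y=%r; skipped", y)
                continue
            predicted = read_predicted_profile(Path(cfg.base_dir, prof_path))
            series = _ensure_uniform(series, sequence)
            results = compute_observables(series, obs_cfg,
                                          predicted_pre=predicted)
            summary.series_analysed += 1
            para = results[-1]
            adir = analysis_dir(root, series.labels[-1], y, "dpre")
            out = adir / f"dpre_{x}.csv"
            write_canonical_csv(para, out)
            manifest.add(out, f"{series.labels[-1]}|{y}|{x}", "result_table")
            dpre_sources[y] = para
            if "dpre_profile" in cfg.plots:
                plot_requests.append(dict(
                    template="dpre_profile", data=para, predicted=predicted,
                    config=PlotConfig(template="dpre_profile"),
                    out_path=analysis_dir(
                        root, series.labels[-1], y, "plots")
                    / "dpre_profile",
                ))

    # ---- comparative stacking ---------------------------------------------
    if len(dpre_sources) > 1:
        for parameter in ("dpre", "smoothed_dpre"):
            ordered = {y: dpre_sources[y] for y in cfg.axes.y
                       if y in dpre_sources}
            table = stack(ordered, parameter, computed_along="z",
                          presented_along="y")
            cdir = analysis_dir(root, "comparative", "all", "stacked")
            cpath = cdir / f"{parameter}_stacked_y.csv"
            table.matrix.to_csv(cpath)
            manifest.add(cpath, "comparative", "stacked_matrix")
            if parameter == "smoothed_dpre" and "heat_map" in cfg.plots:
                plot_requests.append(dict(
                    template="heat_map", data=table,
                    config=PlotConfig(template="heat_map"),
                    out_path=cdir / "heat_map",
                ))
    elif cfg.analyses.dpre and "heat_map" in cfg.plots:
        logger.info("heat map skipped: a single y label has ΔPRE data")

    # ---- figures -----------------------------------------------------------
    produced = render_all(plot_requests)
    summary.figures_written = len(produced)
    for fig_path, sidecar in produced:
        rel = fig_path.relative_to(root)
        coord = "|".join(rel.parts[:2]) if len(rel.parts) > 2 else "-"
        manifest.add(fig_path, coord, "figure")
        manifest.add(sidecar, coord, "sidecar")

    # ---- sidechain tables --------------------------------------------------
    for coord, side in sorted(sidechains.items()):
        z, y, x = coord
        spath = analysis_dir(root, z, y, "sidechains") / f"sidechains_{x}.csv"
        write_canonical_csv(side, spath)
        manifest.add(spath, "|".join(coord), "sidechain_table")
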