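"""Synthetic peaklist datasets with known ground truth.

Two generators emulate the situations the analysis pipeline is built for,
so every stage can be exercised end to end without measured data:

* :func:`simulate_titration` -- a ligand titration of a 100-residue
  protein followed by ¹H-¹⁵N HSQC at seven ligand points (0 → 800 µM).
  Responding residues move in fast exchange, δ(x) = δ_free + f_bound(x)·Δδmax
  with f_bound from a one-site isotherm; some peaks disappear mid-series
  (exchange broadening) and prolines are never observed.
* :func:`simulate_pre_pair` -- a paramagnetic/diamagnetic experiment pair:
  paramagnetic peak heights are the diamagnetic ones multiplied by a
  distance-dependent intensity-ratio profile.  The accompanying *predicted*
  profile contains only the random-coil part, so the ground-truth ΔPRE
  signal is exactly the configured deviation regions.

Default noise: Gaussian shift noise σ = 0.002 ppm (¹H) / 0.02 ppm (¹⁵N),
log-normal 2% height noise.  Everything is deterministic given the seed.
Generated files double as parser golden fixtures: each dataset can be
emitted in every supported dialect.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .peaklist_io import AA1_TO_3, PeakRow, PeaklistTable

_NON_PROLINE = tuple(sorted(set("ACDEFGHIKLMNQRSTVWY")))

DEFAULT_X_POINTS = (0.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0)  # µM


def _format_x(value: float) -> str:
    return format(value, "g")


# ---------------------------------------------------------------------------
# titration

@dataclass
class TitrationSimSpec:
    """Parameters of the simulated ligand titration.

    ``responders`` maps residue number -> (CSPmax_H ppm, CSPmax_X ppm,
    Kd µM); ``disappearing`` maps residue number -> 1-based series point at
    which the peak vanishes (absent from that point on); ``unassigned``
    residues (the prolines by default) never appear.  ``n_responders``
    only applies when ``responders`` is not given explicitly.
    """

    n_residues: int = 100
    x_points: tuple[float, ...] = DEFAULT_X_POINTS
    n_responders: int = 30
    responders: dict[int, tuple[float, float, float]] | None = None
    disappearing: dict[int, int] = field(default_factory=lambda: {22: 4})
    unassigned: tuple[int, ...] | None = None   # None -> the prolines
    n_prolines: int = 5
    noise_sd_shift_h: float = 0.002   # ppm
    noise_sd_shift_x: float = 0.02    # ppm
    noise_sd_height: float = 0.02     # log-normal fraction
    seed: int = 2018

    def __post_init__(self):
        if list(self.x_points) != sorted(set(self.x_points)):
            raise ValueError("x_points must be strictly increasing")
        if any(x < 0 for x in self.x_points):
            raise ValueError("ligand concentrations must be non-negative")


def _draw_sequence(rng: np.random.Generator,
                   spec: TitrationSimSpec) -> dict[int, str]:
    """Random sequence with exactly n_prolines prolines, none at reserved
    residues (responders/disappearing must stay observable)."""
    seq = {i: str(rng.choice(_NON_PROLINE))
           for i in range(1, spec.n_residues + 1)}
    reserved = set(spec.disappearing) | set(spec.responders or {})
    eligible = [i for i in seq if i not in reserved]
    pro = rng.choice(eligible, size=spec.n_prolines, replace=False)
    for i in pro:
        seq[int(i)] = "P"
    return seq


def _draw_responders(
    rng: np.random.Generator, spec: TitrationSimSpec,
    sequence: dict[int, str],
) -> dict[int, tuple[float, float, float]]:
    eligible = [i for i, aa in sequence.items()
                if aa != "P" and i not in spec.disappearing]
    chosen = sorted(
        int(i) for i in rng.choice(
            eligible, size=spec.n_responders, replace=False)
    )
    out = {}
    for num in chosen:
        cspmax_h = float(rng.uniform(0.03, 0.12))     # ppm, 1H
        cspmax_x = float(rng.uniform(0.15, 0.60))     # ppm, 15N
        kd = float(rng.uniform(50.0, 300.0))          # µM
        out[num] = (cspmax_h, cspmax_x, kd)
    return out


def simulate_titration(
    spec: TitrationSimSpec | None = None,
) -> tuple[dict[str, PeaklistTable], pd.DataFrame]:
    """Generate one peaklist per titration point plus the ground truth.

    Returns ``(tables, ground_truth)``: ``tables`` maps the x label (ligand
    concentration as text) to a :class:`PeaklistTable`; the ground-truth
    frame records per residue the free-state shifts, responder parameters,
    vanish point and observability.
    """
    spec = spec or TitrationSimSpec()
    rng = np.random.default_rng(spec.seed)
    sequence = _draw_sequence(rng, spec)
    responders = spec.responders
    if responders is None:
        responders = _draw_responders(rng, spec, sequence)
    unassigned = spec.unassigned
    if unassigned is None:
        unassigned = tuple(i for i, aa in sorted(sequence.items())
                           if aa == "P")

    nums = sorted(sequence)
    free_h = rng.uniform(7.5, 9.2, size=len(nums))
    free_x = rng.uniform(104.0, 127.0, size=len(nums))
    base_height = rng.uniform(0.8e7, 1.6e7, size=len(nums))

    truth = pd.DataFrame({
        "residue_number": nums,
        "residue_type": [sequence[n] for n in nums],
        "free_shift_h": free_h,
        "free_shift_x": free_x,
        "base_height": base_height,
        "is_responder": [n in responders for n in nums],
        "cspmax_h": [responders.get(n, (np.nan,) * 3)[0] for n in nums],
        "cspmax_x": [responders.get(n, (np.nan,) * 3)[1] for n in nums],
        "kd": [responders.get(n, (np.nan,) * 3)[2] for n in nums],
        "vanish_point": [spec.disappearing.get(n, 0) for n in nums],
        "is_unassigned": [n in set(unassigned) for n in nums],
    }).set_index("residue_number", drop=False)

    tables: dict[str, PeaklistTable] = {}
    for point, x in enumerate(spec.x_points, start=1):
        rows: list[PeakRow] = []
        for i, num in enumerate(nums):
            if num in set(unassigned):
                continue
            vanish = spec.disappearing.get(num, 0)
            if vanish and point >= vanish:
                continue
            if num in responders:
                ch, cx, kd = responders[num]
                fbound = x / (kd + x) if (kd + x) > 0 else 0.0
            else:
                ch = cx = fbound = 0.0
            dh = fbound * ch
            dx = fbound * cx
            noise_h = rng.normal(0.0, spec.noise_sd_shift_h) \
                if spec.noise_sd_shift_h else 0.0
            noise_x = rng.normal(0.0, spec.noise_sd_shift_x) \
                if spec.noise_sd_shift_x else 0.0
            hfac = math.exp(rng.normal(0.0, spec.noise_sd_height)) \
                if spec.noise_sd_height else 1.0
            height = base_height[i] * hfac
            rows.append(PeakRow(
                residue_number=num,
                residue_type=sequence[num],
                atom_f1="N", atom_f2="H",
                shift_f1=free_x[i] + dx + noise_x,
                shift_f2=free_h[i] + dh + noise_h,
                height=height,
                volume=height * 2.5,
            ))
        tables[_format_x(x)] = PeaklistTable(
            rows, source_format="synthetic",
            source_path=f"titration_{_format_x(x)}",
        )
    return tables, truth.reset_index(drop=True)


# ---------------------------------------------------------------------------
# paramagnetic pair

@dataclass
class PreSimSpec:
    """Parameters of the simulated paramagnetic/diamagnetic pair.

    The random-coil intensity-ratio profile is a Gaussian well of ``depth``
    and width ``broadening_width`` centred at ``probe_site`` on top of
    ``baseline_ratio``; ``deviation_regions`` [(first, last, extra_depth)]
    multiply in additional broadening that a random coil would *not* show
    (transient contacts), which is exactly the ground-truth ΔPRE signal.
    """

    n_residues: int = 100
    probe_site: int = 10
    broadening_width: float = 6.0     # residues
    depth: float = 0.95               # ratio reduction at the probe
    baseline_ratio: float = 0.95
    deviation_regions: tuple[tuple[int, int, float], ...] = ()
    noise_sd_height: float = 0.02
    seed: int = 2018

    def __post_init__(self):
        if not (0.0 <= self.depth <= 1.0
                and 0.0 <= self.baseline_ratio <= 1.0):
            raise ValueError("ratios must lie in [0, 1]")
        for first, last, extra in self.deviation_regions:
            if not (1 <= first <= last <= self.n_residues):
                raise ValueError(f"bad deviation region {(first, last)}")
            if not 0.0 <= extra <= 1.0:
                raise ValueError("deviation depth must lie in [0, 1]")


def coil_profile(spec: PreSimSpec) -> pd.Series:
    """Predicted random-coil I_para/I_dia profile (no deviations)."""
    nums = np.arange(1, spec.n_residues + 1)
    well = spec.depth * np.exp(
        -((nums - spec.probe_site) ** 2)
        / (2.0 * spec.broadening_width**2)
    )
    prof = spec.baseline_ratio * (1.0 - well)
    return pd.Series(prof, index=nums, name="predicted_ratio")


def simulate_pre_pair(
    spec: PreSimSpec | None = None,
) -> tuple[PeaklistTable, PeaklistTable, pd.Series, pd.DataFrame]:
    """Generate (diamagnetic, paramagnetic, predicted profile, ground truth).

    Paramagnetic heights are diamagnetic heights times the true ratio
    profile (coil well × deviation regions), each height carrying
    independent log-normal noise.  The predicted profile is the coil part
    only, so the expected ΔPRE (predicted − observed ratio) is positive
    exactly inside the deviation regions.
    """
    spec = spec or PreSimSpec()
    rng = np.random.default_rng(spec.seed)
    nums = np.arange(1, spec.n_residues + 1)
    predicted = coil_profile(spec)
    true_ratio = predicted.copy()
    for first, last, extra in spec.deviation_regions:
        sel = (nums >= first) & (nums <= last)
        true_ratio[sel] = true_ratio[sel] * (1.0 - extra)

    seq = {int(i): str(rng.choice(_NON_PROLINE)) for i in nums}
    shift_h = rng.uniform(7.5, 9.2, size=len(nums))
    shift_x = rng.uniform(104.0, 127.0, size=len(nums))
    dia_height = rng.uniform(0.8e7, 1.6e7, size=len(nums))

    def noisy(h: float) -> float:
        if not spec.noise_sd_height:
            return h
        return h * math.exp(rng.normal(0.0, spec.noise_sd_height))

    dia_rows, para_rows = [], []
    for i, num in enumerate(nums):
        num = int(num)
        common = dict(
            residue_number=num, residue_type=seq[num],
            atom_f1="N", atom_f2="H",
            shift_f1=shift_x[i], shift_f2=shift_h[i],
        )
        h_dia = noisy(dia_height[i])
        h_para = noisy(dia_height[i] * float(true_ratio.loc[num]))
        dia_rows.append(PeakRow(**common, height=h_dia,
                                volume=h_dia * 2.5))
        para_rows.append(PeakRow(**common, height=h_para,
                                 volume=h_para * 2.5))
    dia = PeaklistTable(dia_rows, source_format="synthetic",
                        source_path="pre_dia")
    para = PeaklistTable(para_rows, source_format="synthetic",
                         source_path="pre_para")
    truth = pd.DataFrame({
        "residue_number": nums,
        "predicted_ratio": predicted.to_numpy(),
        "true_ratio": true_ratio.to_numpy(),
        "true_dpre": (predicted - true_ratio).to_numpy(),
    })
    return dia, para, predicted, truth


# ---------------------------------------------------------------------------
# dialect emitters (generated files double as parser goldens)

def format_sparky(table: PeaklistTable) -> str:
    lines = ["     Assignment         w1         w2   Data Height     Volume"]
    for row in table:
        ass = f"{row.residue_type}{row.residue_number}" \
              f"{row.atom_f1}-{row.atom_f2}"
        lines.append(
            f"{ass:>15s} {row.shift_f1!r:>22} {row.shift_f2!r:>22} "
            f"{row.height!r:>22} {row.volume!r:>22}"
        )
    return "\n".join(lines) + "\n"


def format_nmrpipe(table: PeaklistTable) -> str:
    lines = [
        "VARS   INDEX X_PPM Y_PPM XW_HZ YW_HZ HEIGHT VOL ASS",
        "FORMAT %5d %10.5f %10.5f %8.3f %8.3f %+e %+e %s",
    ]
    for i, row in enumerate(table, start=1):
        ass = f"{row.residue_type}{row.residue_number}" \
              f"{row.atom_f1}-{row.atom_f2}"
        lw1 = "-" if math.isnan(row.linewidth_f1) else repr(row.linewidth_f1)
        lw2 = "-" if math.isnan(row.linewidth_f2) else repr(row.linewidth_f2)
        lines.append(
            f"{i:5d} {row.shift_f2!r} {row.shift_f1!r} "
            f"{lw2} {lw1} {row.height!r} {row.volume!r} {ass}"
        )
    return "\n".join(lines) + "\n"


def format_ccpnv2(table: PeaklistTable) -> str:
    header = ("Number,Position F1,Position F2,Assign F1,Assign F2,"
              "Height,Volume,Line Width F1 (Hz),Line Width F2 (Hz),"
              "Merit,Details,Fit Method")
    lines = [header]
    for i, row in enumerate(table, start=1):
        res3 = AA1_TO_3[row.residue_type]
        a1 = f"{res3}{row.residue_number}{row.atom_f1}"
        a2 = f"{res3}{row.residue_number}{row.atom_f2}"

        def num(v: float) -> str:
            return "" if math.isnan(v) else repr(v)

        def text(v: str) -> str:
            return f'"{v}"' if "," in v else v

        lines.append(
            f"{i},{num(row.shift_f1)},{num(row.shift_f2)},{a1},{a2},"
            f"{num(row.height)},{num(row.volume)},"
            f"{num(row.linewidth_f1)},{num(row.linewidth_f2)},"
            f"{text(row.merit)},{text(row.details)},{text(row.fit_method)}"
        )
    return "\n".join(lines) + "\n"


def format_nmrview(table: PeaklistTable) -> str:
    lines = [
        "label dataset sw sf",
        "1H 15N",
        "synthetic.nv",
        " 1H.L 1H.P 15N.L 15N.P vol int",
    ]
    for i, row in enumerate(table):
        lines.append(
            f"{i} {{{row.residue_number}.{row.residue_type}.{row.atom_f2}}} "
            f"{row.shift_f2!r} "
            f"{{{row.residue_number}.{row.residue_type}.{row.atom_f1}}} "
            f"{row.shift_f1!r} {row.volume!r} {row.height!r}"
        )
    return "\n".join(lines) + "\n"


DIALECT_WRITERS = {
    "sparky": format_sparky,
    "nmrpipe": format_nmrpipe,
    "ccpnv2": format_ccpnv2,
    "nmrview": format_nmrview,
}


# ---------------------------------------------------------------------------
# on-disk datasets

def write_titration_dataset(
    outdir: str | Path,
    spec: TitrationSimSpec | None = None,
    dialect: str = "sparky",
    all_dialects: bool = False,
) -> Path:
    """Write a complete, ready-to-run titration dataset.

    Produces one peaklist per titration point (in ``dialect``, or every
    dialect under per-format subdirectories with ``all_dialects``), the
    ground-truth table, and a run-configuration file wired to the files.
    Returns the configuration path.
    """
    spec = spec or TitrationSimSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, truth = simulate_titration(spec)
    labels = list(tables)
    manifest: dict[str, str] = {}
    ext = {"sparky": "list", "nmrpipe": "tab",
           "ccpnv2": "csv", "nmrview": "xpk"}
    dialects = list(DIALECT_WRITERS) if all_dialects else [dialect]
    for dia in dialects:
        sub = outdir / dia if all_dialects else outdir
        sub.mkdir(exist_ok=True)
        for lbl in labels:
            path = sub / f"titration_{lbl}.{ext[dia]}"
            path.write_text(DIALECT_WRITERS[dia](tables[lbl]))
            if dia == dialect:
                manifest[lbl] = str(path.relative_to(outdir))
    truth.to_csv(outdir / "ground_truth.csv", index=False)
    seq = "".join(truth.sort_values("residue_number")["residue_type"])
    (outdir / "sequence.fasta").write_text(
        ">synthetic start=1\n" + seq + "\n"
    )
    config = {
        "axes": {
            "x": labels,
            "y": ["construct1"],
            "z": ["ligandA"],
        },
        "peaklists": {
            f"ligandA|construct1|{lbl}": manifest[lbl] for lbl in labels
        },
        "curation": {"sequence": "sequence.fasta"},
        "analyses": {"csp": True, "ratios": True, "fitting": True},
        "plots": ["bar_extended", "residue_evolution"],
        "export": {"chimera_attributes": ["csp"]},
    }
    cfg_path = outdir / "run_config.json"
    cfg_path.write_text(json.dumps(config, indent=2) + "\n")
    return cfg_path


def write_pre_dataset(
    outdir: str | Path,
    specs: dict[str, PreSimSpec] | None = None,
    base_seed: int = 2018,
    n_variants: int = 10,
) -> Path:
    """Write a paramagnetic case-study-shaped dataset.

    One diamagnetic/paramagnetic pair per sequence variant (default 10
    variants → 20 peaklists), a shared predicted random-coil profile per
    variant, and a run-configuration file.  Returns the configuration path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if specs is None:
        specs = {
            f"variant{i + 1:02d}": PreSimSpec(
                seed=base_seed + i,
                deviation_regions=((60, 70, 0.4),) if i % 2 else (),
            )
            for i in range(n_variants)
        }
    peaklists: dict[str, str] = {}
    for name, spec in specs.items():
        dia, para, predicted, _truth = simulate_pre_pair(spec)
        for zlbl, table in (("dia", dia), ("para", para)):
            path = outdir / f"{name}_{zlbl}.list"
            path.write_text(format_sparky(table))
            peaklists[f"{zlbl}|{name}|0"] = path.name
        pred_path = outdir / f"{name}_predicted.csv"
        predicted.rename_axis("residue_number").to_csv(pred_path)
    config = {
        "axes": {"x": ["0"], "y": sorted(specs), "z": ["dia", "para"]},
        "peaklists": peaklists,
        "analyses": {"csp": False, "ratios": True, "dpre": True},
        "dpre": {
            "predicted_profiles": {
                name: f"{name}_predicted.csv" for name in specs
            }
        },
        "plots": ["dpre_profile", "heat_map"],
        "export": {},
    }
    cfg_path = outdir / "run_config.json"
    cfg_path.write_text(json.dumps(config, indent=2) + "\n")
    return cfg_path
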