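"""Per-residue derived NMR parameters along a normalized series.

Every observable is computed by comparing a target peaklist against the
series reference, which is always the *first* experiment in the series.

Implemented quantities
----------------------
* Δδ per nucleus (ppm) and the weighted combined chemical shift
  perturbation ``CSP = sqrt(0.5 * (Δδ_H² + (α · Δδ_X)²))`` with the
  conventional heteronucleus weight α = 0.14 (0.2 for glycine) for ¹⁵N.
* Height and volume ratios I/I₀.
* ΔPRE: deviation of the observed paramagnetic/diamagnetic intensity-ratio
  profile from the profile predicted by a random-coil conformational model.
  Sign convention (configurable): ΔPRE = predicted − observed, so positive
  values mark residues *more* broadened than the random-coil expectation.
* Running Gaussian convolution smoothing of per-residue profiles, with
  edge/gap renormalization of the kernel weights.
* Per-spectrum chemical-shift renormalization against a reference residue.

All functions operate on :class:`pandas.Series` indexed by residue number;
NaN means "no value" and is propagated, never replaced by an invented
number.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cube import Series
from .peaklist_io import STATUS_MEASURED, PeaklistTable, ResultTable

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.14
GLYCINE_ALPHA = 0.2


@dataclass
class ObservableConfig:
    """Knobs for the observable calculations.

    ``alpha_map`` holds per-residue-type overrides of the heteronucleus
    weight; anything not listed uses ``alpha_default``.  Smoothing defaults:
    σ = 3 residues, half-width = ceil(4σ).
    """

    alpha_default: float = DEFAULT_ALPHA
    alpha_map: dict[str, float] = field(
        default_factory=lambda: {"G": GLYCINE_ALPHA}
    )
    ratio_kind: str = "height"
    smoothing_sigma: float = 3.0
    smoothing_halfwidth: int | None = None   # None -> ceil(4 sigma)
    significance_threshold: float | None = None
    dpre_sign: int = 1     # +1: predicted - observed; -1: observed - predicted

    def __post_init__(self):
        if self.alpha_default <= 0:
            raise ValueError("alpha must be > 0")
        if self.smoothing_sigma <= 0:
            raise ValueError("smoothing sigma must be > 0")
        if self.ratio_kind not in ("height", "volume"):
            raise ValueError(f"ratio_kind {self.ratio_kind!r}")
        if self.dpre_sign not in (1, -1):
            raise ValueError("dpre_sign must be +1 or -1")

    @property
    def halfwidth(self) -> int:
        if self.smoothing_halfwidth is not None:
            if self.smoothing_halfwidth < 1:
                raise ValueError("smoothing halfwidth must be >= 1")
            return self.smoothing_halfwidth
        return math.ceil(4 * self.smoothing_sigma)

    def alpha_for(self, residue_type: str) -> float:
        return self.alpha_map.get(residue_type, self.alpha_default)


def _indexed(table: PeaklistTable, column: str) -> pd.Series:
    return table.frame.set_index("residue_number")[column]


# ---------------------------------------------------------------------------
# chemical shifts

def delta_shifts(
    reference: PeaklistTable, target: PeaklistTable
) -> tuple[pd.Series, pd.Series]:
    """Δδ per nucleus: ``(target − reference)`` in ppm.

    Returns ``(delta_h, delta_x)`` — the ¹H (f2) and heteronucleus (f1)
    differences — indexed by residue number.  Both tables must already be
    normalized to the same residue index; that is the curation contract.
    """
    ref, tgt = reference.frame, target.frame
    if not np.array_equal(
        ref["residue_number"].to_numpy(), tgt["residue_number"].to_numpy()
    ):
        raise ValueError(
            "reference and target tables have different residue indices; "
            "run curation first"
        )
    delta_h = _indexed(target, "shift_f2") - _indexed(reference, "shift_f2")
    delta_x = _indexed(target, "shift_f1") - _indexed(reference, "shift_f1")
    return delta_h.rename("delta_h"), delta_x.rename("delta_x")


def combined_csp(
    delta_h: pd.Series,
    delta_x: pd.Series,
    alpha: float | pd.Series = DEFAULT_ALPHA,
) -> pd.Series:
    """Weighted combined chemical shift perturbation.

    ``csp = sqrt(0.5 * (Δδ_H² + (α · Δδ_X)²))``; α may be a scalar or a
    per-residue series (glycines conventionally get 0.2 instead of 0.14).
    """
    if isinstance(alpha, pd.Series):
        alpha = alpha.reindex(delta_h.index)
    csp = np.sqrt(0.5 * (delta_h**2 + (alpha * delta_x) ** 2))
    return pd.Series(csp, index=delta_h.index, name="csp")


def alpha_series(
    table: PeaklistTable, config: ObservableConfig
) -> pd.Series:
    """Per-residue α weights from residue types (default/glycine/overrides)."""
    types = _indexed(table, "residue_type")
    return types.map(config.alpha_for).astype(float)


# ---------------------------------------------------------------------------
# intensities

def intensity_ratio(
    reference: PeaklistTable, target: PeaklistTable, kind: str = "height"
) -> pd.Series:
    """Per-residue intensity ratio ``target / reference``.

    ``kind`` selects the height or volume column.  A zero or absent
    reference value yields NaN (with a warning), never infinity.
    """
    if kind not in ("height", "volume"):
        raise ValueError(f"ratio kind must be height or volume, got {kind!r}")
    ref = _indexed(reference, kind)
    tgt = _indexed(target, kind)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = tgt / ref.where(ref != 0)
    n_zero = int(((ref == 0) & tgt.notna()).sum())
    if n_zero:
        logger.warning(
            "%d residues have zero reference %s; ratio left empty",
            n_zero, kind,
        )
    return ratio.rename(f"{kind}_ratio")


# ---------------------------------------------------------------------------
# paramagnetic deviation

def dpre(
    observed_ratio: pd.Series,
    predicted_ratio: pd.Series,
    sign: int = 1,
    tolerance: float = 0.15,
) -> pd.Series:
    """ΔPRE: deviation of observed I_para/I_dia from the random-coil model.

    With ``sign=+1`` (default) the value is ``predicted − observed``:
    positive means more broadening (more contact/compaction) than a random
    coil predicts.  Residues present in only one profile yield NaN with a
    warning.  Ratios are expected in [0, 1 + tolerance].
    """
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    for name, prof in (("observed", observed_ratio),
                       ("predicted", predicted_ratio)):
        vals = prof.dropna()
        if ((vals < 0) | (vals > 1 + tolerance)).any():
            bad = vals[(vals < 0) | (vals > 1 + tolerance)]
            raise ValueError(
                f"{name} intensity ratios outside [0, {1 + tolerance}]: "
                f"residues {list(bad.index[:5])}"
            )
    index = observed_ratio.index.union(predicted_ratio.index)
    obs = observed_ratio.reindex(index)
    pred = predicted_ratio.reindex(index)
    only_one = (obs.isna() ^ pred.isna())
    if only_one.any():
        logger.warning(
            "%d residues present in only one PRE profile; ΔPRE left empty",
            int(only_one.sum()),
        )
    return (sign * (pred - obs)).rename("dpre")


def read_predicted_profile(path) -> pd.Series:
    """Predicted random-coil PRE profile from a two-column table.

    Accepts CSV or whitespace-delimited ``residue_number  predicted_ratio``
    with '#' comment lines (e.g. a statistical-coil ensemble prediction).
    """
    frame = pd.read_csv(
        path, sep=None, engine="python", comment="#",
        names=["residue_number", "predicted_ratio"], header=None,
    )
    # tolerate a header row
    if not np.issubdtype(
        pd.to_numeric(frame["residue_number"], errors="coerce").dtype,
        np.number,
    ) or pd.to_numeric(frame["residue_number"], errors="coerce").isna().any():
        frame = frame.iloc[1:]
    prof = pd.Series(
        pd.to_numeric(frame["predicted_ratio"]).to_numpy(),
        index=pd.to_numeric(frame["residue_number"]).astype(int).to_numpy(),
        name="predicted_ratio",
    )
    return prof.sort_index()


# ---------------------------------------------------------------------------
# smoothing

def gaussian_smooth(
    profile: pd.Series, sigma: float = 3.0, halfwidth: int | None = None
) -> pd.Series:
    """Running Gaussian convolution filter over a per-residue profile.

    ``s_i = Σ_j w_j v_{i+j} / Σ_j w_j`` with ``w_j = exp(−j²/(2σ²))`` over
    the window ``j ∈ [−halfwidth, halfwidth]`` restricted to residues that
    carry a value; weights renormalize at sequence edges and across gaps, so
    a constant profile is returned unchanged.  Offsets are taken in residue
    *number* space, so assignment gaps widen in sequence, not in row count.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if halfwidth is None:
        halfwidth = math.ceil(4 * sigma)
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    values = profile.dropna()
    if values.empty:
        return pd.Series(np.nan, index=profile.index, name="smoothed")
    idx = values.index.to_numpy(dtype=float)
    vals = values.to_numpy(dtype=float)
    out = pd.Series(np.nan, index=profile.index, dtype=float,
                    name="smoothed")
    for i in profile.index:
        offs = idx - i
        window = np.abs(offs) <= halfwidth
        if not window.any():
            continue
        w = np.exp(-(offs[window] ** 2) / (2.0 * sigma**2))
        out.at[i] = float(np.dot(w, vals[window]) / w.sum())
    return out


# ---------------------------------------------------------------------------
# shift normalization

def shift_normalize(series: Series, reference_residue: int) -> Series:
    """Remove per-spectrum global shift offsets using one reference residue.

    The (Δδ_H, Δδ_X) of ``reference_residue`` relative to the series
    reference spectrum is subtracted from *all* residues of each spectrum,
    so the reference residue's CSP becomes exactly zero at every point.
    Useful when a buffer/temperature artefact shifts a whole spectrum.
    Idempotent.  The reference residue must be measured at every point.
    """
    bad_points = [
        lbl for lbl, t in zip(series.labels, series.tables)
        if not (
            (t.frame["residue_number"] == reference_residue)
            & (t.frame["status"] == STATUS_MEASURED)
        ).any()
    ]
    if bad_points:
        raise ValueError(
            f"reference residue {reference_residue} is not measured at "
            f"points {bad_points}"
        )
    ref_table = series.reference
    ref_h = float(_indexed(ref_table, "shift_f2").loc[reference_residue])
    ref_x = float(_indexed(ref_table, "shift_f1").loc[reference_residue])
    new_tables = []
    for table in series.tables:
        off_h = float(
            _indexed(table, "shift_f2").loc[reference_residue]) - ref_h
        off_x = float(
            _indexed(table, "shift_f1").loc[reference_residue]) - ref_x
        frame = table.frame.copy()
        frame["shift_f2"] = frame["shift_f2"] - off_h
        frame["shift_f1"] = frame["shift_f1"] - off_x
        new_tables.append(table.replace_frame(frame))
    return Series(
        along=series.along, fixed=series.fixed, labels=series.labels,
        tables=new_tables, numeric_values=series.numeric_values,
    )


# ---------------------------------------------------------------------------
# series-level driver

def compute_observables(
    series: Series,
    config: ObservableConfig | None = None,
    predicted_pre: pd.Series | None = None,
) -> list[ResultTable]:
    """Derive all configured observables for every table of a series.

    Each returned :class:`ResultTable` is the normalized input table with
    derived columns appended (``delta_h``, ``delta_x``, ``csp``,
    ``height_ratio`` or ``volume_ratio``; plus ``dpre`` and
    ``smoothed_dpre`` when a predicted PRE profile is supplied and the
    series is a dia/para pair along z).  Derived values are empty for
    unassigned rows.
    """
    config = config or ObservableConfig()
    reference = series.reference
    alphas = alpha_series(reference, config)
    results: list[ResultTable] = []
    for table in series.tables:
        dh, dx = delta_shifts(reference, table)
        csp = combined_csp(dh, dx, alphas)
        ratio = intensity_ratio(reference, table, config.ratio_kind)
        frame = table.frame.copy().set_index("residue_number", drop=False)
        frame["delta_h"] = dh
        frame["delta_x"] = dx
        frame["csp"] = csp
        frame[f"{config.ratio_kind}_ratio"] = ratio
        unassigned = frame["status"] == "unassigned"
        derived = ["delta_h", "delta_x", "csp", f"{config.ratio_kind}_ratio"]
        if predicted_pre is not None and table is not reference:
            profile = dpre(
                ratio, predicted_pre, sign=config.dpre_sign
            ).reindex(frame.index)
            frame["dpre"] = profile
            frame["smoothed_dpre"] = gaussian_smooth(
                frame["dpre"], config.smoothing_sigma, config.halfwidth
            )
            derived += ["dpre", "smoothed_dpre"]
        frame.loc[unassigned, derived] = np.nan
        result = table.replace_frame(frame.reset_index(drop=True))
        results.append(result)
    return results
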