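"""Per-residue fitting of observable-vs-x titration curves.

In the fast-exchange regime the observed CSP of a residue follows the bound
fraction of the protein, so fitting the CSP against ligand concentration
yields an apparent dissociation constant per residue.  Two standard models
ship built in and custom models can be registered:

* ``hill``:  csp(x) = CSPmax · xⁿ / (Kdⁿ + xⁿ)  (n = 1 recovers the
  one-site non-depleting hyperbola).
* ``one_site_depletion``: the exact one-site quadratic that accounts for
  ligand depletion at protein concentration P₀.

Fitting is restricted to continuous (numeric, monotonic) x data; the axis
policy enforces that upstream.  Failures never raise: a residue that cannot
be fit is reported with ``converged=False`` and a reason.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .peaklist_io import STATUS_MEASURED, ResultTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# models

def hill_model(x: np.ndarray, cspmax: float, kd: float, n: float
               ) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        return cspmax * x**n / (kd**n + x**n)


def one_site_depletion_model(
    x: np.ndarray, cspmax: float, kd: float, protein_conc: float
) -> np.ndarray:
    """Exact one-site binding with ligand depletion at protein conc P0."""
    x = np.asarray(x, dtype=float)
    p0 = protein_conc
    b = p0 + x + kd
    frac = (b - np.sqrt(b**2 - 4.0 * p0 * x)) / (2.0 * p0)
    return cspmax * frac


#: registry so users can plug in their own fitting routines
MODEL_REGISTRY: dict[str, Callable] = {
    "hill": hill_model,
    "one_site_depletion": one_site_depletion_model,
}


def register_model(name: str, func: Callable) -> None:
    """Register a custom model ``f(x, *params) -> y`` under ``name``."""
    MODEL_REGISTRY[name] = func


@dataclass
class FitResult:
    residue_number: int
    model: str
    params: dict[str, float] = field(default_factory=dict)
    rmse: float = math.nan
    converged: bool = False
    n_points_used: int = 0
    reason: str = ""

    def as_record(self) -> dict:
        rec = {
            "residue_number": self.residue_number,
            "model": self.model,
            "rmse": self.rmse,
            "converged": self.converged,
            "n_points_used": self.n_points_used,
            "reason": self.reason,
        }
        rec.update(self.params)
        return rec


@dataclass
class FitConfig:
    model: str = "hill"
    protein_conc: float | None = None    # required for one_site_depletion
    fix_hill_n: bool = False             # n pinned to 1
    response_floor: float | None = None  # None -> 3 x median noise estimate
    min_points: int = 4
    curve_grid_points: int = 100


# ---------------------------------------------------------------------------
# single residue

def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(CSPmax0, Kd0): max response and x at half-max by linear interpolation."""
    cspmax0 = float(np.nanmax(y))
    if cspmax0 <= 0:
        return max(cspmax0, 1e-12), float(np.median(x[x > 0])) \
            if (x > 0).any() else 1.0
    half = cspmax0 / 2.0
    kd0 = float(x[-1])
    for i in range(1, len(y)):
        if y[i] >= half:
            x0, x1, y0, y1 = x[i - 1], x[i], y[i - 1], y[i]
            kd0 = float(x0 + (half - y0) * (x1 - x0) / (y1 - y0)) \
                if y1 != y0 else float(x1)
            break
    return cspmax0, max(kd0, 1e-9)


def fit_residue(
    x_values: Sequence[float],
    observable: Sequence[float],
    model: str = "hill",
    init: Sequence[float] | None = None,
    config: FitConfig | None = None,
    residue_number: int = 0,
) -> FitResult:
    """Least-squares fit of one residue's observable against x.

    Requires at least ``config.min_points`` finite points and strictly
    increasing numeric x.  Never raises on fit failure; returns
    ``converged=False`` with a diagnostic reason instead.
    """
    config = config or FitConfig(model=model)
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(observable, dtype=float)
    if np.isnan(x).any():
        raise ValueError("x values must be numeric (axis policy violation)")
    keep = ~np.isnan(y)
    x, y = x[keep], y[keep]
    result = FitResult(residue_number=residue_number, model=model,
                       n_points_used=int(keep.sum()))
    if len(x) < config.min_points:
        result.reason = "insufficient points"
        return result
    if (np.diff(x) <= 0).any():
        raise ValueError("x values must be strictly increasing")

    cspmax0, kd0 = _initial_guess(x, y)
    if model == "hill":
        if config.fix_hill_n:
            func = lambda xx, a, k: hill_model(xx, a, k, 1.0)  # noqa: E731
            p0 = init or (cspmax0, kd0)
            bounds = ([0.0, 1e-12], [np.inf, np.inf])
            names = ["cspmax", "kd"]
        else:
            func = hill_model
            p0 = init or (cspmax0, kd0, 1.0)
            bounds = ([0.0, 1e-12, 0.05], [np.inf, np.inf, 20.0])
            names = ["cspmax", "kd", "hill_n"]
    elif model == "one_site_depletion":
        if config.protein_conc is None:
            result.reason = "protein concentration required for depletion model"
            return result
        pc = config.protein_conc
        func = lambda xx, a, k: one_site_depletion_model(xx, a, k, pc)  # noqa
        p0 = init or (cspmax0, kd0)
        bounds = ([0.0, 1e-12], [np.inf, np.inf])
        names = ["cspmax", "kd"]
    elif model in MODEL_REGISTRY:
        func = MODEL_REGISTRY[model]
        if init is None:
            result.reason = "custom models require an explicit init"
            return result
        p0 = init
        bounds = (-np.inf, np.inf)
        names = [f"p{i}" for i in range(len(p0))]
    else:
        result.reason = f"unknown model {model!r}"
        return result

    if len(x) < len(p0) + 1:
        result.reason = "insufficient points"
        return result
    try:
        popt, _ = curve_fit(
            func, x, y, p0=p0, bounds=bounds, method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
        )
    except Exception as exc:
        result.reason = f"optimizer failure: {exc}"
        return result
    resid = y - func(x, *popt)
    result.params = dict(zip(names, (float(v) for v in popt)))
    result.rmse = float(np.sqrt(np.mean(resid**2)))
    result.converged = True
    if "hill_n" not in result.params and model in (
        "hill", "one_site_depletion"
    ):
        result.params.setdefault("hill_n", 1.0)
    return result


# ---------------------------------------------------------------------------
# series level

def estimate_noise(matrix: pd.DataFrame) -> float:
    """Noise floor from second differences of each residue's response.

    For a smooth titration curve the second difference along x is dominated
    by noise; its standard deviation relates to the point noise by √6.
    Returns the median over residues (0 when nothing can be estimated).
    """
    ests = []
    for _, row in matrix.iterrows():
        vals = row.dropna().to_numpy(dtype=float)
        if len(vals) >= 4:
            d2 = np.diff(vals, n=2)
            if len(d2):
                ests.append(np.std(d2) / math.sqrt(6.0))
    return float(np.median(ests)) if ests else 0.0


def observable_matrix(
    results: Sequence[ResultTable], labels: Sequence[str],
    column: str = "csp", measured_only: bool = True,
) -> pd.DataFrame:
    """Residue × series-point matrix of one derived column.

    With ``measured_only`` carried (missing) and unassigned values are
    masked out so fits never see fabricated points.
    """
    cols = {}
    for lbl, table in zip(labels, results):
        frame = table.frame.set_index("residue_number")
        vals = frame[column]
        if measured_only:
            vals = vals.where(frame["status"] == STATUS_MEASURED)
        cols[lbl] = vals
    return pd.DataFrame(cols)


def fit_series(
    results: Sequence[ResultTable],
    x_values: Sequence[float],
    labels: Sequence[str],
    config: FitConfig | None = None,
    column: str = "csp",
) -> tuple[list[FitResult], pd.DataFrame, pd.DataFrame]:
    """Fit every eligible residue of a series.

    Returns ``(fits, fits_table, curves)``: per-residue results, a tidy
    one-row-per-residue DataFrame, and fitted curves sampled on a
    100-point x grid for plotting.  Residues whose maximum response is
    below the response floor (default 3× the median noise estimate) are
    reported unfitted rather than fitted to noise.
    """
    config = config or FitConfig()
    matrix = observable_matrix(results, labels, column=column)
    x = np.asarray(x_values, dtype=float)
    floor = config.response_floor
    if floor is None:
        floor = 3.0 * estimate_noise(matrix)
    fits: list[FitResult] = []
    grid = np.linspace(float(x.min()), float(x.max()),
                       config.curve_grid_points)
    curve_cols: dict[int, np.ndarray] = {}
    for num, row in matrix.iterrows():
        y = row.to_numpy(dtype=float)
        if np.isnan(y).all():
            fits.append(FitResult(
                residue_number=int(num), model=config.model,
                reason="no data (unassigned)",
            ))
            continue
        if np.nanmax(np.abs(y)) < floor:
            res = fit_residue(x, y, model=config.model, config=config,
                              residue_number=int(num))
            if res.converged:
                res.reason = "no response"
            fits.append(res)
            continue
        res = fit_residue(x, y, model=config.model, config=config,
                          residue_number=int(num))
        fits.append(res)
        if res.converged and res.model == "hill":
            curve_cols[int(num)] = hill_model(
                grid, res.params["cspmax"], res.params["kd"],
                res.params.get("hill_n", 1.0),
            )
        elif res.converged and res.model == "one_site_depletion":
            curve_cols[int(num)] = one_site_depletion_model(
                grid, res.params["cspmax"], res.params["kd"],
                config.protein_conc,
            )
    skipped = [f.residue_number for f in fits if not f.converged]
    if skipped:
        logger.info("skipped/unconverged residues: %s", skipped)
    fits_table = pd.DataFrame([f.as_record() for f in fits])
    curves = pd.DataFrame(curve_cols, index=grid)
    curves.index.name = "x"
    return fits, fits_table, curves
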