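"""Piecewise-linear dependence of the inter-peak delay on plate thickness.

Above a breakpoint thickness ``d_f`` the delay ``tau`` is flat at ``tau0``
(the plate is rigid enough that its thickness no longer matters); below it,
``tau`` rises linearly as the plate thins::

    tau~(Th) = tau0                      if Th > d_f
             = tau0 + k_f * (Th - d_f)   if Th <= d_f        (k_f < 0)

The three parameters are estimated by minimising the mean absolute
deviation between per-location mean ``tau`` values and the model, using
restarted Nelder-Mead simplex searches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "PiecewiseParams",
    "PiecewiseFit",
    "LocationSummary",
    "piecewise_tau",
    "cost_e_tau",
    "fit_piecewise",
    "aggregate_thickness",
    "summarize_locations",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = [
    "plate_id",
    "location_index",
    "mean_tau_ms",
    "sd_tau_ms",
    "mean_thickness_mm",
    "sd_thickness_mm",
    "procedure",
]


@dataclass(frozen=True)
class PiecewiseParams:
    """Parameters of the piecewise-linear tau(thickness) law.

    tau0 : plateau delay, ms.  d_f : breakpoint thickness, mm.
    k_f : slope below the breakpoint, ms/mm (negative for a delay that
    grows as the plate thins).
    """

    tau0: float
    d_f: float
    k_f: float

    def __post_init__(self) -> None:
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")
        if self.d_f <= 0:
            raise ValueError("d_f must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.tau0, self.d_f, self.k_f], dtype=float)


@dataclass(frozen=True)
class PiecewiseFit:
    """Result of a piecewise fit: parameters, residual cost, design size."""

    params: PiecewiseParams
    e_tau: float
    n_locations: int
    breakpoint_identified: bool = True

    def __post_init__(self) -> None:
        if self.e_tau < 0:
            raise ValueError("E_tau must be non-negative")


@dataclass(frozen=True)
class LocationSummary:
    """Per-location means of tau (Bone impacts only) and thickness."""

    plate_id: str
    location_index: int
    mean_tau_ms: float
    sd_tau_ms: float
    mean_thickness_mm: float
    sd_thickness_mm: float
    procedure: str = "thickness_assessment"


def piecewise_tau(
    thickness_mm: float | np.ndarray, params: PiecewiseParams
) -> float | np.ndarray:
    """Evaluate the piecewise-linear law; continuous at ``Th = d_f``."""
    th = np.asarray(thickness_mm, dtype=float)
    if np.any(th < 0):
        raise ValueError("thickness must be non-negative")
    out = np.where(
        th > params.d_f,
        params.tau0,
        params.tau0 + params.k_f * (th - params.d_f),
    )
    return float(out) if np.isscalar(thickness_mm) else out


def _summary_arrays(
    locations: Sequence[LocationSummary] | pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(locations, pd.DataFrame):
        tau = locations["mean_tau_ms"].to_numpy(float)
        th = locations["mean_thickness_mm"].to_numpy(float)
    else:
        tau = np.array([loc.mean_tau_ms for loc in locations], float)
        th = np.array([loc.mean_thickness_mm for loc in locations], float)
    if tau.size == 0:
        raise ValueError("no locations supplied")
    return tau, th


def cost_e_tau(
    params: PiecewiseParams,
    locations: Sequence[LocationSummary] | pd.DataFrame,
) -> float:
    """Mean absolute residual between location means and the model (ms)."""
    tau, th = _summary_arrays(locations)
    return float(np.mean(np.abs(tau - piecewise_tau(th, params))))


def _default_initial(tau: np.ndarray, th: np.ndarray) -> np.ndarray:
    """Heuristic start: plateau from thickest tercile, slope from thinnest."""
    order = np.argsort(th)
    n = th.size
    thick = order[-max(2, n // 3):]
    thin = order[: max(2, n // 3)]
    tau0 = float(np.median(tau[thick]))
    d_f = float(np.median(th))
    if np.ptp(th[thin]) > 0:
        k_f = float(np.polyfit(th[thin], tau[thin], 1)[0])
    else:
        k_f = -0.5
    if k_f >= 0:
        k_f = -0.1
    return np.array([tau0, d_f, k_f])


def fit_piecewise(
    locations: Sequence[LocationSummary] | pd.DataFrame,
    initial: PiecewiseParams | None = None,
    restarts: int = 10,
    seed: int = 0,
    fatol: float = 1e-6,
    max_iterations: int = 2000,
) -> PiecewiseFit:
    """Fit the piecewise law by restarted Nelder-Mead simplex minimisation.

    ``restarts`` additional runs start from multiplicatively jittered
    (±20%) copies of the initial guess; the lowest-cost solution wins, with
    ties broken towards the smallest breakpoint ``d_f``.  The fitted
    breakpoint is clamped to the observed thickness range.  When every
    observed thickness sits above the fitted breakpoint the slope is
    unconstrained by the data and the fit is flagged
    ``breakpoint_identified=False`` (with a warning).
    """
    tau, th = _summary_arrays(locations)
    if tau.size < 4:
        raise ValueError("need at least 4 locations to fit the piecewise model")
    th_lo, th_hi = float(np.min(th)), float(np.max(th))

    def objective(x: np.ndarray) -> float:
        tau0, d_f, k_f = x
        penalty = 0.0
        if tau0 <= 0:
            penalty += 1e3 * (1 - tau0)
            tau0 = 1e-6
        if d_f < th_lo:
            penalty += 1e2 * (th_lo - d_f)
            d_f = th_lo
        elif d_f > th_hi:
            penalty += 1e2 * (d_f - th_hi)
            d_f = th_hi
        model = np.where(th > d_f, tau0, tau0 + k_f * (th - d_f))
        return float(np.mean(np.abs(tau - model))) + penalty

    x0 = initial.as_array() if initial is not None else _default_initial(tau, th)
    initial_cost = objective(x0)

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, restarts)):
        starts.append(x0 * rng.uniform(0.8, 1.2, size=3))

    best_x, best_cost = None, np.inf
    for start in starts:
        res = minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={"fatol": fatol, "xatol": 1e-8, "maxiter": max_iterations},
        )
        cost, x = float(res.fun), res.x
        if cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-9 and best_x is not None and x[1] < best_x[1]
        ):
            best_cost, best_x = cost, x

    if best_x is None or best_cost > initial_cost + 1e-12:
        warnings.warn("Nelder-Mead failed to improve on the initial parameters")
        best_x = x0
    tau0, d_f, k_f = float(best_x[0]), float(best_x[1]), float(best_x[2])
    d_f = float(np.clip(d_f, th_lo, th_hi))
    params = PiecewiseParams(tau0=tau0, d_f=d_f, k_f=k_f)
    # The breakpoint is only supported when both regimes are populated and
    # the rising branch is distinguishable from flat.
    n_below = int(np.sum(th <= d_f + 1e-12))
    n_above = int(np.sum(th > d_f))
    identified = n_below >= 2 and n_above >= 2 and abs(k_f) >= 0.05
    if not identified:
        warnings.warn(
            "breakpoint d_f is not identified: all locations fall in one regime"
        )
    return PiecewiseFit(
        params=params,
        e_tau=cost_e_tau(params, locations),
        n_locations=int(tau.size),
        breakpoint_identified=identified,
    )


def aggregate_thickness(
    calliper: pd.DataFrame,
    extents: pd.DataFrame,
) -> pd.DataFrame:
    """Pool repeated calliper measures into per-location thickness stats.

    ``calliper`` holds the raw gauge readings taken repeatedly along the
    plate (columns ``plate_id, x_mm, thickness_mm``; typically 5 repeats
    every 2.5 mm).  ``extents`` gives each location's x-range (columns
    ``plate_id, procedure, location_index, x_min_mm, x_max_mm``).  All
    measures whose position falls inside a location's closed interval are
    pooled into that location's mean/sd.
    """
    rows = []
    for ext in extents.itertuples(index=False):
        plate = calliper[calliper["plate_id"] == ext.plate_id]
        sel = plate[
            (plate["x_mm"] >= ext.x_min_mm) & (plate["x_mm"] <= ext.x_max_mm)
        ]["thickness_mm"]
        if sel.empty:
            raise ValueError(
                "no calliper measurements overlap location "
                f"{ext.plate_id}/{ext.procedure}/{ext.location_index}"
            )
        rows.append(
            {
                "plate_id": ext.plate_id,
                "procedure": ext.procedure,
                "location_index": ext.location_index,
                "mean_thickness_mm": float(sel.mean()),
                "sd_thickness_mm": float(sel.std(ddof=1)) if sel.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def summarize_locations(
    indicators: pd.DataFrame,
    thickness: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-impact indicators with per-location thickness.

    ``indicators`` needs columns ``plate_id, procedure, location_index,
    tau_ms, label``; only ``Bone``-labelled impacts enter the tau means
    (crossing blows no longer probe the plate).  ``thickness`` is the output
    of :func:`aggregate_thickness`.
    """
    bone = indicators[indicators["label"] == "Bone"]
    stats = (
        bone.groupby(["plate_id", "procedure", "location_index"])["tau_ms"]
        .agg(mean_tau_ms="mean", sd_tau_ms=lambda s: s.std(ddof=1) if s.size > 1 else 0.0)
        .reset_index()
    )
    merged = stats.merge(
        thickness, on=["plate_id", "procedure", "location_index"], how="inner"
    )
    return merged[
        [
            "plate_id",
            "location_index",
            "mean_tau_ms",
            "sd_tau_ms",
            "mean_thickness_mm",
            "sd_thickness_mm",
            "procedure",
        ]
    ]
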