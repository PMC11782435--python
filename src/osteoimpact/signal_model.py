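"""Per-impact force-signal analysis.

Each hammer blow on the osteotome produces a force-vs-time trace ``s(t)``
whose first two peaks carry the mechanical information exploited by the
pipeline: the inter-peak delay ``tau`` (ms) reflects the rigidity of the
material at the osteotome tip (the second peak is the rebound of the
osteotome between bone and hammer), and the impulse ratio
``lambda = L2 / L1`` of the Gaussian-fitted peak areas is linked to the
viscoelasticity of that material.  ``tau`` rises and ``lambda`` drops
suddenly when the osteotome crosses the bone plate.

This module extracts those indicators per impact and assembles the
per-impact feature table (``tau``, ``lambda`` and their first differences
``dtau``, ``dlambda``) with Bone / Crossing labels used downstream by the
thickness regression and the classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.optimize import curve_fit

__all__ = [
    "ImpactSignal",
    "PeakFit",
    "PeakDetectionError",
    "GaussianFitError",
    "detect_first_two_peaks",
    "fit_gaussian_peak",
    "compute_tau",
    "compute_lambda",
    "extract_indicators",
    "build_feature_table",
    "differences_from_indicators",
    "read_signal_csv",
    "write_signal_csv",
    "FEATURE_COLUMNS",
]

MS_PER_S = 1e3
SQRT_2PI = math.sqrt(2.0 * math.pi)

#: Column layout of the per-impact feature table (CSV interface).
FEATURE_COLUMNS = [
    "plate_id",
    "location_index",
    "impact_index",
    "tau_ms",
    "lambda",
    "dtau_ms",
    "dlambda",
    "label",
]


class PeakDetectionError(ValueError):
    """Raised when a trace does not contain two usable force peaks."""


class GaussianFitError(RuntimeError):
    """Raised when the Gaussian peak fit fails or returns nonsense."""


@dataclass(frozen=True)
class ImpactSignal:
    """One force-vs-time trace for one hammer blow.

    Parameters
    ----------
    time
        Sample times in seconds, strictly increasing, uniformly spaced at
        ``1 / sampling_rate``.
    force
        Force in newtons, same length as ``time``, finite everywhere.
    sampling_rate
        Acquisition rate in Hz (51.2 kHz for the reference hardware).
    plate_id, location_index, impact_index
        Provenance of the blow; ``impact_index`` is 1-based within the
        plate's procedure sequence.
    procedure
        ``"thickness_assessment"`` (low-energy probing blows) or
        ``"osteotomy"`` (cutting blows until rupture).
    """

    time: np.ndarray
    force: np.ndarray
    sampling_rate: float
    plate_id: str = "?"
    location_index: int = 1
    impact_index: int = 1
    procedure: str = "osteotomy"

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        force = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "force", force)
        if time.ndim != 1 or force.shape != time.shape:
            raise ValueError("time and force must be 1-D arrays of equal length")
        if time.size < 64:
            raise ValueError(f"signal too short: {time.size} samples (< 64)")
        if not np.all(np.isfinite(force)):
            raise ValueError("force contains non-finite samples")
        dt = np.diff(time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        expected = 1.0 / self.sampling_rate
        if np.max(np.abs(dt - expected)) > 1e-9:
            raise ValueError("time grid is not uniform at 1/sampling_rate")
        if self.procedure not in ("thickness_assessment", "osteotomy"):
            raise ValueError(f"unknown procedure {self.procedure!r}")
        if self.impact_index < 1 or self.location_index < 1:
            raise ValueError("impact_index and location_index are 1-based")

    @property
    def time_ms(self) -> np.ndarray:
        return self.time * MS_PER_S

    @property
    def n_samples(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class PeakFit:
    """Gaussian approximation of one force peak.

    ``integral`` is the closed-form Gaussian area
    ``L_p = sqrt(2*pi) * width * amplitude`` (newton·ms), with ``width``
    the Gaussian standard deviation in ms.
    """

    center_ms: float
    amplitude_n: float
    width_ms: float
    rank: int = 1
    integral: float = field(init=False)

    def __post_init__(self) -> None:
        # Zero amplitude encodes a vanished (second) peak; the fit routine
        # itself never returns one.
        if self.amplitude_n < 0:
            raise ValueError("peak amplitude must be non-negative")
        if self.width_ms <= 0:
            raise ValueError("peak width must be positive")
        if self.rank not in (1, 2):
            raise ValueError("rank must be 1 or 2")
        object.__setattr__(
            self, "integral", SQRT_2PI * self.width_ms * self.amplitude_n
        )


def detect_first_two_peaks(
    signal: ImpactSignal,
    min_prominence_fraction: float = 0.10,
    min_separation_ms: float = 0.10,
) -> tuple[int, int]:
    """Locate the first two force peaks of a trace.

    Local maxima are accepted when their prominence is at least
    ``min_prominence_fraction`` of the global force maximum and they are at
    least ``min_separation_ms`` apart; the prominence floor rejects sensor
    ripple.  The two earliest qualifying maxima are returned as sample
    indices in time order.

    Raises
    ------
    PeakDetectionError
        If fewer than two qualifying peaks exist.
    """
    if not 0.0 < min_prominence_fraction < 1.0:
        raise ValueError("min_prominence_fraction must lie in (0, 1)")
    force = signal.force
    prominence = min_prominence_fraction * float(np.max(force))
    distance = max(1, int(round(min_separation_ms * 1e-3 * signal.sampling_rate)))
    peaks, _ = sp_signal.find_peaks(force, prominence=prominence, distance=distance)
    if peaks.size < 2:
        raise PeakDetectionError(
            "insufficient peaks: found "
            f"{peaks.size} qualifying peak(s) in impact "
            f"{signal.plate_id}/{signal.impact_index}"
        )
    first, second = int(peaks[0]), int(peaks[1])
    return first, second


def _gaussian(t: np.ndarray, a: float, c: float, w: float) -> np.ndarray:
    return a * np.exp(-((t - c) ** 2) / (2.0 * w**2))


def fit_gaussian_peak(
    signal: ImpactSignal,
    peak_index: int,
    window_halfwidth_ms: float = 0.30,
    rank: int = 1,
) -> PeakFit:
    """Least-squares Gaussian fit ``a * exp(-(t - c)^2 / (2 w^2))`` around a peak.

    The fit window is ``peak_index`` ± ``window_halfwidth_ms`` truncated at
    the signal edges.  Initialisation uses the raw maximum for amplitude and
    center and the half width at half maximum divided by 1.177 for the
    Gaussian standard deviation.

    Raises
    ------
    GaussianFitError
        On non-convergence, or if the fitted amplitude leaves the window's
        force range by more than 50% or the fitted width leaves
        ``(0, window span]``.
    """
    t_ms = signal.time_ms
    half_samples = int(round(window_halfwidth_ms * 1e-3 * signal.sampling_rate))
    lo = max(0, peak_index - half_samples)
    hi = min(signal.n_samples, peak_index + half_samples + 1)
    if hi - lo < 5:
        raise GaussianFitError("fit failed: window holds fewer than 5 samples")
    tw = t_ms[lo:hi]
    fw = signal.force[lo:hi]

    a0 = float(signal.force[peak_index])
    c0 = float(t_ms[peak_index])
    if a0 <= 0:
        raise GaussianFitError("fit failed: non-positive raw peak amplitude")
    # HWHM of a Gaussian is sigma * sqrt(2 ln 2) ~= 1.177 sigma.
    above = np.flatnonzero(fw >= 0.5 * a0)
    if above.size >= 2:
        hwhm = 0.5 * (tw[above[-1]] - tw[above[0]])
    else:
        hwhm = 0.25 * (tw[-1] - tw[0])
    w0 = max(hwhm / 1.177, (tw[1] - tw[0]))

    try:
        popt, _ = curve_fit(
            _gaussian, tw, fw, p0=(a0, c0, w0), maxfev=5000
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message varies
        raise GaussianFitError(f"fit failed: {exc}") from exc
    a, c, w = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    span = float(tw[-1] - tw[0])
    force_range = float(np.max(fw) - np.min(fw))
    if not (0.0 < w <= span):
        raise GaussianFitError(f"fit failed: width {w:.4g} ms outside (0, {span:.4g}]")
    if a <= 0 or abs(a - np.max(fw)) > 0.5 * max(force_range, np.max(fw)):
        raise GaussianFitError("fit failed: amplitude outside window force range ±50%")
    return PeakFit(center_ms=c, amplitude_n=a, width_ms=w, rank=rank)


def compute_tau(first_peak: PeakFit, second_peak: PeakFit) -> float:
    """Inter-peak delay ``tau`` in ms (second peak center minus first)."""
    tau = second_peak.center_ms - first_peak.center_ms
    if tau <= 0:
        raise ValueError(
            f"peak ordering error: second center {second_peak.center_ms:.4f} ms "
            f"not after first {first_peak.center_ms:.4f} ms"
        )
    return tau


def compute_lambda(first_peak: PeakFit, second_peak: PeakFit) -> float:
    """Impulse ratio ``lambda = L2 / L1`` of the Gaussian peak areas."""
    if first_peak.integral <= 0:
        raise ZeroDivisionError("first peak integral L1 is zero")
    return second_peak.integral / first_peak.integral


def extract_indicators(
    signal: ImpactSignal,
    min_prominence_fraction: float = 0.10,
    min_separation_ms: float = 0.10,
    window_halfwidth_ms: float = 0.30,
    use_fit_centers: bool = True,
) -> tuple[float, float]:
    """Extract ``(tau, lambda)`` from one trace.

    ``tau`` is taken between the Gaussian-fit centers by default;
    ``use_fit_centers=False`` switches to the raw sample maxima.
    """
    i1, i2 = detect_first_two_peaks(signal, min_prominence_fraction, min_separation_ms)
    p1 = fit_gaussian_peak(signal, i1, window_halfwidth_ms, rank=1)
    p2 = fit_gaussian_peak(signal, i2, window_halfwidth_ms, rank=2)
    if use_fit_centers:
        tau = compute_tau(p1, p2)
    else:
        tau = (signal.time_ms[i2] - signal.time_ms[i1])
        if tau <= 0:
            raise ValueError("peak ordering error on raw maxima")
    lam = compute_lambda(p1, p2)
    return tau, lam


def build_feature_table(
    signals: Sequence[ImpactSignal],
    crossing_marks: Sequence[bool],
    **extract_kwargs,
) -> pd.DataFrame:
    """Assemble the per-impact feature table from an ordered impact sequence.

    ``crossing_marks`` flags, per impact, both the blow on which the
    operator felt the osteotome cross the plate and the single additional
    post-rupture blow; those impacts are labelled ``Crossing``, every other
    one ``Bone``.

    The first impact of each plate is dropped (its differences are
    undefined); for impact ``i > 1``, ``dtau(i) = tau(i) - tau(i-1)`` and
    ``dlambda(i) = lambda(i) - lambda(i-1)`` are taken against the
    immediately preceding impact of the same plate, across osteotomy-location
    boundaries.
    """
    if len(signals) != len(crossing_marks):
        raise ValueError("signals and crossing_marks must have equal length")
    rows = []
    for sig, crossing in zip(signals, crossing_marks):
        tau, lam = extract_indicators(sig, **extract_kwargs)
        rows.append(
            {
                "plate_id": sig.plate_id,
                "location_index": sig.location_index,
                "impact_index": sig.impact_index,
                "tau_ms": tau,
                "lambda": lam,
                "label": "Crossing" if crossing else "Bone",
            }
        )
    raw = pd.DataFrame(rows)
    return differences_from_indicators(raw)


def differences_from_indicators(indicators: pd.DataFrame) -> pd.DataFrame:
    """Derive the Delta features from a per-impact indicator table.

    Expects columns ``plate_id, location_index, impact_index, tau_ms,
    lambda, label`` ordered per plate; adds ``dtau_ms`` and ``dlambda``
    against the immediately preceding impact of the same plate and drops
    each plate's first impact, whose differences are undefined.
    """
    out = []
    for plate_id, grp in indicators.groupby("plate_id", sort=False):
        idx = grp["impact_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            raise ValueError(
                f"integrity error: impact indices for plate {plate_id!r} "
                "are unordered or duplicated"
            )
        g = grp.copy()
        g["dtau_ms"] = g["tau_ms"].diff()
        g["dlambda"] = g["lambda"].diff()
        out.append(g.iloc[1:])  # first impact per plate has no differences
    table = pd.concat(out, ignore_index=True)
    return table[FEATURE_COLUMNS]


def read_signal_csv(path: str | Path, sampling_rate: float | None = None, **meta) -> ImpactSignal:
    """Load one impact trace from a ``time_s,force_N`` CSV file."""
    df = pd.read_csv(path)
    if not {"time_s", "force_N"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s,force_N")
    time = df["time_s"].to_numpy(float)
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
    return ImpactSignal(
        time=time, force=df["force_N"].to_numpy(float), sampling_rate=sampling_rate, **meta
    )


def write_signal_csv(signal: ImpactSignal, path: str | Path) -> None:
    """Write one impact trace as a ``time_s,force_N`` CSV file."""
    pd.DataFrame({"time_s": signal.time, "force_N": signal.force}).to_csv(
        path, index=False, float_format="%.9g"
    )
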