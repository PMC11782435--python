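"""Seeded synthetic impact experiments.

No public dataset of instrumented-hammer osteotomy signals exists, so this
module generates complete experiments with the statistical structure the
analysis assumes, making every downstream stage testable offline:

* each blow is a two-Gaussian force pulse (initial hammer-osteotome
  contact, then the rebound of the osteotome between bone and hammer);
* the bone-phase inter-peak delay follows the piecewise-linear
  tau(thickness) law, so thinning plates push tau off its plateau;
* at plate crossing, tau jumps up and lambda drops multiplicatively, and
  each osteotomy location ends with exactly one crossing blow plus one
  additional post-rupture blow (both labelled "Crossing");
* per-plate experiment structure (number of osteotomy locations, blows per
  location, low-energy thickness-assessment series, repeated calliper
  thickness readings along the plate) is drawn to match the defaults in
  :class:`GeneratorConfig`.

The generator is phenomenological: it emulates the observable signal
statistics, not the contact mechanics of the hammer-osteotome-bone system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .signal_model import ImpactSignal, MS_PER_S
from .thickness_model import PiecewiseParams, piecewise_tau

__all__ = [
    "GeneratorConfig",
    "SyntheticExperiment",
    "generate_impact_signal",
    "generate_osteotomy_location",
    "generate_thickness_assessment",
    "generate_database",
    "generate_overlapping_projection",
    "generate_location_cloud",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "plate_id",
    "location_index",
    "impact_index",
    "procedure",
    "crossing",
    "flag_extra_post_rupture",
    "true_thickness_mm",
    "true_effective_thickness_mm",
    "true_tau_ms",
    "true_lambda",
]

SENSOR_RANGE_N = 4450.0  # compression range of the force sensor


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic experiments.

    The defaults encode the reference experiment: 16 plates; 3-5 osteotomy
    locations per plate (mean 3.52); blows per location decreasing with
    location rank (means 14.60, 10.32, 7.83, 7.94, 8.00 with sds 12.82,
    4.66, 3.60, 3.32, 2.83); a tau plateau of 0.95 ms with breakpoint
    1.2 mm and slope -0.89 ms/mm; low-energy blows peaking between 100 and
    200 N; 51.2 kHz sampling over 20 ms.
    """

    seed: int = 0
    n_plates: int = 16
    # Osteotomy structure
    location_count_values: tuple[int, ...] = (3, 4, 5)
    location_count_probs: tuple[float, ...] = (0.5452, 0.3903, 0.0645)
    impacts_per_location_mean: tuple[float, ...] = (14.60, 10.32, 7.83, 7.94, 8.00)
    impacts_per_location_sd: tuple[float, ...] = (12.82, 4.66, 3.60, 3.32, 2.83)
    min_impacts_per_location: int = 4
    max_impacts_per_location: int = 45
    # tau(thickness) truth and noise
    tau0_ms: float = 0.95
    d_f_mm: float = 1.2
    k_f_ms_per_mm: float = -0.89
    tau_noise_sd_ms: float = 0.03
    # Crossing effect sizes
    crossing_tau_jump_mean_ms: float = 0.5
    crossing_tau_jump_sd_ms: float = 0.1
    lambda_bone_mean: float = 0.6
    lambda_bone_sd: float = 0.1
    crossing_lambda_drop: tuple[float, float] = (0.3, 0.7)
    # Plate geometry and damage
    thickness_start_mm: float = 3.0
    thickness_end_mm: float = 0.5
    thickness_jitter_sd_mm: float = 0.05
    damage_exponent: float = 4.0
    # Thickness-assessment structure
    ta_locations_mean: float = 5.65
    ta_locations_sd: float = 0.98
    ta_impacts_per_location: int = 5
    ta_step_mm: float = 3.0  # half the 6-mm blade
    osteotomy_step_mm: float = 6.0  # full blade length
    # Calliper protocol
    calliper_step_mm: float = 2.5
    calliper_repeats: int = 5
    calliper_noise_sd_mm: float = 0.05
    # Pulse shape / acquisition
    first_peak_amplitude_n: tuple[float, float] = (100.0, 200.0)
    osteotomy_amplitude_n: tuple[float, float] = (200.0, 600.0)
    peak_width_ms: tuple[float, float] = (0.12, 0.18)
    first_peak_time_ms: float = 1.0
    force_noise_sd_n: float = 0.0
    sampling_rate_hz: float = 51.2e3
    duration_ms: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "tau_noise_sd_ms",
            "crossing_tau_jump_sd_ms",
            "lambda_bone_sd",
            "thickness_jitter_sd_mm",
            "calliper_noise_sd_mm",
            "force_noise_sd_n",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.d_f_mm <= 0:
            raise ValueError("d_f_mm must be positive")
        if self.k_f_ms_per_mm >= 0:
            raise ValueError("k_f_ms_per_mm must be negative")
        for rng_ in (self.first_peak_amplitude_n, self.osteotomy_amplitude_n):
            if not (0.0 < rng_[0] <= rng_[1] <= SENSOR_RANGE_N):
                raise ValueError(
                    f"amplitude range {rng_} outside sensor range (0, {SENSOR_RANGE_N}] N"
                )
        if abs(sum(self.location_count_probs) - 1.0) > 1e-9:
            raise ValueError("location_count_probs must sum to 1")
        if self.min_impacts_per_location < 3:
            raise ValueError("locations need at least 3 impacts (2 crossing + 1 bone)")

    @property
    def piecewise_truth(self) -> PiecewiseParams:
        return PiecewiseParams(self.tau0_ms, self.d_f_mm, self.k_f_ms_per_mm)


@dataclass(frozen=True)
class SyntheticExperiment:
    """Generated signals plus ground-truth bookkeeping.

    ``manifest`` has one row per signal (see :data:`MANIFEST_COLUMNS`),
    ``calliper`` the repeated thickness gauge readings along each plate, and
    ``extents`` each location's x-range for calliper pooling.
    """

    signals: tuple[ImpactSignal, ...]
    manifest: pd.DataFrame
    calliper: pd.DataFrame
    extents: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.signals) != len(self.manifest):
            raise ValueError("manifest row count must equal signal count")


def generate_impact_signal(
    tau_true_ms: float,
    lambda_true: float,
    a1_n: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    *,
    plate_id: str = "?",
    location_index: int = 1,
    impact_index: int = 1,
    procedure: str = "osteotomy",
) -> ImpactSignal:
    """One two-Gaussian force pulse with prescribed (tau, lambda, a1).

    The first Gaussian (amplitude ``a1_n``) sits near 1 ms; the second sits
    ``tau_true_ms`` later with area ``lambda_true`` times the first's, so
    the extracted indicators round-trip to the requested values on
    noise-free settings.
    """
    if tau_true_ms <= 0:
        raise ValueError("tau_true_ms must be positive")
    if lambda_true < 0:
        raise ValueError("lambda_true must be non-negative")
    w1 = rng.uniform(*config.peak_width_ms)
    w2 = rng.uniform(*config.peak_width_ms)
    if tau_true_ms < 3.0 * max(w1, w2):
        raise ValueError(
            f"peaks unresolvable: tau={tau_true_ms:.3f} ms < 3 pulse widths"
        )
    n = int(round(config.duration_ms * 1e-3 * config.sampling_rate_hz))
    t_s = np.arange(n) / config.sampling_rate_hz
    t_ms = t_s * MS_PER_S
    c1 = config.first_peak_time_ms
    c2 = c1 + tau_true_ms
    # Equal areas scale as w*a, so a2 follows from the requested ratio.
    a2 = lambda_true * a1_n * w1 / w2
    force = a1_n * np.exp(-((t_ms - c1) ** 2) / (2 * w1**2)) + a2 * np.exp(
        -((t_ms - c2) ** 2) / (2 * w2**2)
    )
    if config.force_noise_sd_n > 0:
        force = force + rng.normal(0.0, config.force_noise_sd_n, size=n)
    return ImpactSignal(
        time=t_s,
        force=force,
        sampling_rate=config.sampling_rate_hz,
        plate_id=plate_id,
        location_index=location_index,
        impact_index=impact_index,
        procedure=procedure,
    )


def _bone_lambda(config: GeneratorConfig, rng: np.random.Generator) -> float:
    return float(
        np.clip(rng.normal(config.lambda_bone_mean, config.lambda_bone_sd), 0.05, None)
    )


def generate_osteotomy_location(
    thickness_mm: float,
    n_impacts: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    *,
    plate_id: str = "?",
    location_index: int = 1,
    impact_index_start: int = 1,
) -> list[tuple[ImpactSignal, dict]]:
    """Blow sequence for one osteotomy location, ending in rupture.

    A damage variable rises monotonically from 0 to 1 across the location
    (as a power of the blow number, so the structure weakens slowly at
    first and fails abruptly); the effective thickness is
    ``thickness * (1 - damage)`` and bone-phase tau follows the piecewise
    law at that effective thickness plus Gaussian noise.  The final two
    blows are the crossing and the post-rupture check: both are labelled
    Crossing, with tau raised by the crossing jump and lambda multiplied by
    the crossing drop factor.
    """
    if n_impacts < 3:
        raise ValueError("an osteotomy location needs at least 3 impacts")
    truth = config.piecewise_truth
    out: list[tuple[ImpactSignal, dict]] = []
    damage = (np.arange(n_impacts) / (n_impacts - 1)) ** config.damage_exponent
    for i in range(n_impacts):
        crossing = i >= n_impacts - 2
        extra = i == n_impacts - 1
        eff = thickness_mm * (1.0 - damage[i])
        lam = _bone_lambda(config, rng)
        if crossing:
            eff = 0.0
            tau = (
                piecewise_tau(0.0, truth)
                + rng.normal(config.crossing_tau_jump_mean_ms, config.crossing_tau_jump_sd_ms)
                + rng.normal(0.0, config.tau_noise_sd_ms)
            )
            lam *= rng.uniform(*config.crossing_lambda_drop)
        else:
            tau = piecewise_tau(eff, truth) + rng.normal(0.0, config.tau_noise_sd_ms)
        tau = max(tau, 0.55)  # keep peaks resolvable under extreme noise draws
        a1 = rng.uniform(*config.osteotomy_amplitude_n)
        sig = generate_impact_signal(
            tau,
            lam,
            a1,
            config,
            rng,
            plate_id=plate_id,
            location_index=location_index,
            impact_index=impact_index_start + i,
            procedure="osteotomy",
        )
        out.append(
            (
                sig,
                {
                    "plate_id": plate_id,
                    "location_index": location_index,
                    "impact_index": impact_index_start + i,
                    "procedure": "osteotomy",
                    "crossing": bool(crossing),
                    "flag_extra_post_rupture": bool(extra),
                    "true_thickness_mm": float(thickness_mm),
                    "true_effective_thickness_mm": float(eff),
                    "true_tau_ms": float(tau),
                    "true_lambda": float(lam),
                },
            )
        )
    return out


def generate_thickness_assessment(
    thickness_profile_mm: Sequence[float],
    config: GeneratorConfig,
    rng: np.random.Generator,
    *,
    plate_id: str = "?",
) -> list[tuple[ImpactSignal, dict]]:
    """Low-energy probing series: 5 gentle blows per location, no rupture.

    tau is drawn from the piecewise law at the (undamaged) local thickness
    plus noise; amplitudes stay in the low-energy range so the plate is not
    damaged, and every blow is labelled Bone.
    """
    truth = config.piecewise_truth
    out: list[tuple[ImpactSignal, dict]] = []
    impact_index = 1
    for loc, th in enumerate(thickness_profile_mm, start=1):
        for _ in range(config.ta_impacts_per_location):
            tau = piecewise_tau(float(th), truth) + rng.normal(0.0, config.tau_noise_sd_ms)
            tau = max(tau, 0.55)
            lam = _bone_lambda(config, rng)
            a1 = rng.uniform(*config.first_peak_amplitude_n)
            sig = generate_impact_signal(
                tau,
                lam,
                a1,
                config,
                rng,
                plate_id=plate_id,
                location_index=loc,
                impact_index=impact_index,
                procedure="thickness_assessment",
            )
            out.append(
                (
                    sig,
                    {
                        "plate_id": plate_id,
                        "location_index": loc,
                        "impact_index": impact_index,
                        "procedure": "thickness_assessment",
                        "crossing": False,
                        "flag_extra_post_rupture": False,
                        "true_thickness_mm": float(th),
                        "true_effective_thickness_mm": float(th),
                        "true_tau_ms": float(tau),
                        "true_lambda": float(lam),
                    },
                )
            )
            impact_index += 1
    return out


def _plate_profile(x_mm: np.ndarray, length_mm: float, config: GeneratorConfig) -> np.ndarray:
    """Thickness decreasing linearly from the plate root to its free edge."""
    frac = np.clip(x_mm / length_mm, 0.0, 1.0)
    return config.thickness_start_mm + frac * (
        config.thickness_end_mm - config.thickness_start_mm
    )


def generate_database(config: GeneratorConfig) -> SyntheticExperiment:
    """Full seeded experiment over ``config.n_plates`` plates.

    Each plate gets a thickness-assessment series, an osteotomy sequence
    (locations advancing one blade length at a time along the thinning
    plate, each ending in rupture), and a table of repeated calliper
    readings along its x-axis.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    signals: list[ImpactSignal] = []
    records: list[dict] = []
    calliper_rows: list[dict] = []
    extent_rows: list[dict] = []

    for p in range(config.n_plates):
        plate_id = f"P{p + 1:02d}"
        n_ta = int(
            np.clip(round(rng.normal(config.ta_locations_mean, config.ta_locations_sd)), 4, 8)
        )
        n_osteo = int(
            rng.choice(config.location_count_values, p=config.location_count_probs)
        )
        length = max(n_ta * config.ta_step_mm, n_osteo * config.osteotomy_step_mm)

        # Calliper protocol: repeated readings along the x-axis.
        grid = np.arange(0.0, length + 1e-9, config.calliper_step_mm)
        true_at_grid = _plate_profile(grid, length, config)
        for x, th in zip(grid, true_at_grid):
            for _ in range(config.calliper_repeats):
                calliper_rows.append(
                    {
                        "plate_id": plate_id,
                        "x_mm": float(x),
                        "thickness_mm": float(
                            max(th + rng.normal(0.0, config.calliper_noise_sd_mm), 0.05)
                        ),
                    }
                )

        # Thickness assessment: one location per half blade length.
        ta_centers = (np.arange(n_ta) + 0.5) * config.ta_step_mm
        ta_thickness = _plate_profile(ta_centers, length, config) + rng.normal(
            0.0, config.thickness_jitter_sd_mm, size=n_ta
        )
        ta_thickness = np.clip(ta_thickness, 0.1, None)
        for j in range(n_ta):
            extent_rows.append(
                {
                    "plate_id": plate_id,
                    "procedure": "thickness_assessment",
                    "location_index": j + 1,
                    "x_min_mm": float(j * config.ta_step_mm),
                    "x_max_mm": float((j + 1) * config.ta_step_mm),
                }
            )
        for sig, rec in generate_thickness_assessment(
            ta_thickness, config, rng, plate_id=plate_id
        ):
            signals.append(sig)
            records.append(rec)

        # Osteotomy: full blade steps, each location impacted to rupture.
        osteo_centers = (np.arange(n_osteo) + 0.5) * config.osteotomy_step_mm
        osteo_thickness = np.clip(
            _plate_profile(osteo_centers, length, config)
            + rng.normal(0.0, config.thickness_jitter_sd_mm, size=n_osteo),
            0.1,
            None,
        )
        impact_index = 1
        for j in range(n_osteo):
            rank = min(j, len(config.impacts_per_location_mean) - 1)
            n_impacts = int(
                np.clip(
                    round(
                        rng.normal(
                            config.impacts_per_location_mean[rank],
                            config.impacts_per_location_sd[rank],
                        )
                    ),
                    config.min_impacts_per_location,
                    config.max_impacts_per_location,
                )
            )
            extent_rows.append(
                {
                    "plate_id": plate_id,
                    "procedure": "osteotomy",
                    "location_index": j + 1,
                    "x_min_mm": float(j * config.osteotomy_step_mm),
                    "x_max_mm": float((j + 1) * config.osteotomy_step_mm),
                }
            )
            for sig, rec in generate_osteotomy_location(
                float(osteo_thickness[j]),
                n_impacts,
                config,
                rng,
                plate_id=plate_id,
                location_index=j + 1,
                impact_index_start=impact_index,
            ):
                signals.append(sig)
                records.append(rec)
            impact_index += n_impacts

    return SyntheticExperiment(
        signals=tuple(signals),
        manifest=pd.DataFrame(records, columns=MANIFEST_COLUMNS),
        calliper=pd.DataFrame(calliper_rows),
        extents=pd.DataFrame(extent_rows),
    )


def generate_location_cloud(
    n_locations: int,
    params: PiecewiseParams,
    noise_sd_ms: float,
    rng: np.random.Generator,
    thickness_range_mm: tuple[float, float] = (0.3, 3.0),
) -> pd.DataFrame:
    """Per-location (thickness, mean tau) cloud drawn from the piecewise law.

    Thicknesses are uniform over ``thickness_range_mm`` (spanning both the
    plateau and the rising regime for the default truths) and tau values
    are the model plus Gaussian noise.  Returned as a location-summary
    frame ready for :func:`~osteoimpact.thickness_model.fit_piecewise`.
    """
    th = rng.uniform(*thickness_range_mm, size=n_locations)
    tau = piecewise_tau(th, params) + rng.normal(0.0, noise_sd_ms, size=n_locations)
    return pd.DataFrame(
        {
            "plate_id": ["sim"] * n_locations,
            "location_index": np.arange(1, n_locations + 1),
            "mean_tau_ms": tau,
            "sd_tau_ms": noise_sd_ms,
            "mean_thickness_mm": th,
            "sd_thickness_mm": 0.0,
            "procedure": "thickness_assessment",
        }
    )


def generate_overlapping_projection(
    n: int = 600,
    positive_fraction: float = 0.15,
    separation: float = 1.6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Imbalanced overlapping two-class point cloud in the canonical plane.

    Emulates the projected (c1, c2) database of a harder experiment: a
    minority Crossing class (default 15% of records) offset by
    ``separation`` standard deviations from the Bone majority along c1,
    with unit isotropic noise, so the classes overlap and false negatives
    occur.  Used to study the cost-matrix trade-off in isolation.
    """
    if not 0.0 < positive_fraction < 1.0:
        raise ValueError("positive_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_pos = max(1, int(round(n * positive_fraction)))
    n_neg = n - n_pos
    X_neg = rng.normal(0.0, 1.0, size=(n_neg, 2))
    X_pos = rng.normal(0.0, 1.0, size=(n_pos, 2)) + np.array([separation, 0.0])
    X = np.vstack([X_neg, X_pos])
    y = np.array(["Bone"] * n_neg + ["Crossing"] * n_pos)
    order = rng.permutation(n)
    return X[order], y[order]
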