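"""End-to-end orchestration: simulate -> extract -> fit-thickness -> train.

Every random operation traces back to the single top-level seed in
:class:`RunConfig`, and rerunning with the same config reproduces the
CSV/JSON payloads byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (
    CostMatrix,
    anova_oneway,
    canonical_projection,
    crossing_detection_rate,
    kfold_cv,
    nlr,
    optimize_cost_matrix,
)
from .signal_model import (
    FEATURE_COLUMNS,
    differences_from_indicators,
    extract_indicators,
    read_signal_csv,
    write_signal_csv,
)
from .synthetic_data import GeneratorConfig, SyntheticExperiment, generate_database
from .thickness_model import (
    SUMMARY_COLUMNS,
    aggregate_thickness,
    fit_piecewise,
    summarize_locations,
)

__all__ = [
    "RunConfig",
    "PipelineReport",
    "PipelineStageError",
    "run_pipeline",
    "extract_experiment",
    "load_experiment_dir",
    "write_experiment",
    "train_report",
]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the failing stage's name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    ``seed`` governs the generator, the fit restarts and the CV folds;
    generator settings live in ``generator`` (its own seed is overridden by
    the run seed).
    """

    out_dir: str | Path = "osteoimpact_run"
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    k_folds: int = 5
    svm_c: float = 1.0
    optimize_sigma: bool = True
    sigma_grid: tuple[float, ...] = tuple(np.arange(1.0, 10.0 + 1e-9, 0.25))
    fit_restarts: int = 10
    extraction: dict[str, Any] = field(default_factory=dict)
    write_signals: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        gen = raw.pop("generator", {})
        if isinstance(gen, dict):
            gen = GeneratorConfig(**gen)
        if "sigma_grid" in raw:
            raw["sigma_grid"] = tuple(float(s) for s in raw["sigma_grid"])
        return cls(generator=gen, **raw)

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "generator": dataclasses.asdict(self.generator),
            "k_folds": self.k_folds,
            "svm_c": self.svm_c,
            "optimize_sigma": self.optimize_sigma,
            "sigma_grid": list(self.sigma_grid),
            "fit_restarts": self.fit_restarts,
            "extraction": self.extraction,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class PipelineReport:
    """In-memory results of a full run (also serialised to out_dir)."""

    features: pd.DataFrame
    summaries: pd.DataFrame
    thickness_fits: dict[str, dict]
    classification: dict
    log: dict


def extract_experiment(
    experiment: SyntheticExperiment, **extract_kwargs
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract (tau, lambda) for every signal and build the feature table.

    Returns ``(indicators, features)``: indicators has one row per impact
    of either procedure; features is the osteotomy Delta-feature table with
    Bone/Crossing labels from the manifest.
    """
    rows = []
    for sig, rec in zip(experiment.signals, experiment.manifest.itertuples(index=False)):
        tau, lam = extract_indicators(sig, **extract_kwargs)
        rows.append(
            {
                "plate_id": rec.plate_id,
                "procedure": rec.procedure,
                "location_index": rec.location_index,
                "impact_index": rec.impact_index,
                "tau_ms": tau,
                "lambda": lam,
                "label": "Crossing" if rec.crossing else "Bone",
            }
        )
    indicators = pd.DataFrame(rows)
    osteo = indicators[indicators["procedure"] == "osteotomy"].drop(columns="procedure")
    features = differences_from_indicators(osteo)
    return indicators, features


def train_report(
    features: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    sigma_grid=None,
    optimize_sigma: bool = True,
    svm_c: float = 1.0,
) -> dict:
    """Project, cross-validate and (optionally) tune the cost matrix.

    Returns a JSON-ready report with pooled confusion counts, pooled and
    fold-averaged accuracy, the NLR, the selected cost matrix, the
    canonical weight vectors, ANOVA F/p for tau and lambda between classes,
    and the crossing detection rate within one impact.
    """
    proj = canonical_projection(features)
    X2 = proj.transform(features)
    y = features["label"].to_numpy()

    if optimize_sigma:
        search = optimize_cost_matrix(
            X2, y, k=k, seed=seed, sigma_grid=sigma_grid, C=svm_c
        )
        best_cost = search.cost
        counts = search.counts
        extras = {
            "nlr_unweighted": search.nlr_unweighted,
            "counts_unweighted": dataclasses.asdict(search.counts_unweighted),
            "sigma_grid": list(search.grid),
            "nlr_curve": list(search.nlr_curve),
        }
    else:
        best_cost = CostMatrix()
        counts = kfold_cv(X2, y, best_cost, k=k, seed=seed, C=svm_c).counts
        extras = {}

    cv = kfold_cv(X2, y, best_cost, k=k, seed=seed, C=svm_c)
    f_tau, p_tau = anova_oneway(features["tau_ms"].to_numpy(), y)
    f_lam, p_lam = anova_oneway(features["lambda"].to_numpy(), y)
    report = {
        "counts": dataclasses.asdict(counts),
        "accuracy": counts.accuracy,
        "per_fold_accuracy": list(cv.per_fold_accuracy),
        "mean_fold_accuracy": cv.mean_fold_accuracy,
        "nlr": nlr(counts),
        "sigma": {
            "BB": best_cost.sigma_bb,
            "CB": best_cost.sigma_cb,
            "BC": best_cost.sigma_bc,
            "CC": best_cost.sigma_cc,
        },
        "c1_weights": dict(zip(proj.feature_names, proj.c1.tolist())),
        "c2_weights": dict(zip(proj.feature_names, proj.c2.tolist())),
        "anova": {
            "tau": {"F": f_tau, "p": p_tau},
            "lambda": {"F": f_lam, "p": p_lam},
        },
        "crossing_detection_rate": crossing_detection_rate(features, cv.predictions),
        **extras,
    }
    return report


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.9g")


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute all stages in order and write the report bundle.

    Outputs under ``config.out_dir``: ``features.csv``, ``summaries.csv``,
    ``thickness_fit.json``, ``classification_report.json`` and
    ``run_log.json`` (seed, config hash, library versions).  Stage failures
    abort with the failing stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        gen_config = dataclasses.replace(config.generator, seed=config.seed)
        experiment = generate_database(gen_config)
        if config.write_signals:
            write_experiment(experiment, out)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("simulate", str(exc)) from exc

    try:
        indicators, features = extract_experiment(experiment, **config.extraction)
    except Exception as exc:
        raise PipelineStageError("extract", str(exc)) from exc

    try:
        thickness = aggregate_thickness(experiment.calliper, experiment.extents)
        summaries = summarize_locations(indicators, thickness)
        fits = {}
        for proc, grp in summaries.groupby("procedure"):
            fit = fit_piecewise(grp, restarts=config.fit_restarts, seed=config.seed)
            fits[proc] = {
                "tau0_ms": fit.params.tau0,
                "d_f_mm": fit.params.d_f,
                "k_f_ms_per_mm": fit.params.k_f,
                "E_tau": fit.e_tau,
                "P": fit.n_locations,
                "breakpoint_identified": fit.breakpoint_identified,
            }
    except Exception as exc:
        raise PipelineStageError("fit-thickness", str(exc)) from exc

    try:
        classification = train_report(
            features,
            k=config.k_folds,
            seed=config.seed,
            sigma_grid=np.asarray(config.sigma_grid),
            optimize_sigma=config.optimize_sigma,
            svm_c=config.svm_c,
        )
    except Exception as exc:
        raise PipelineStageError("train", str(exc)) from exc

    import scipy
    import sklearn

    log = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_signals": len(experiment.signals),
        "versions": {
            "osteoimpact": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }

    _csv(features[FEATURE_COLUMNS], out / "features.csv")
    _csv(summaries[SUMMARY_COLUMNS], out / "summaries.csv")
    _write_json(out / "thickness_fit.json", fits)
    _write_json(out / "classification_report.json", classification)
    _write_json(out / "run_log.json", log)

    return PipelineReport(
        features=features,
        summaries=summaries,
        thickness_fits=fits,
        classification=classification,
        log=log,
    )


def write_experiment(experiment: SyntheticExperiment, out_dir: str | Path) -> Path:
    """Write signals as per-impact CSVs plus manifest/calliper/extents CSVs."""
    out = Path(out_dir)
    sig_dir = out / "signals"
    sig_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sig in experiment.signals:
        tag = "ta" if sig.procedure == "thickness_assessment" else "ost"
        name = f"{sig.plate_id}_{tag}_{sig.impact_index:04d}.csv"
        write_signal_csv(sig, sig_dir / name)
        paths.append(f"signals/{name}")
    manifest = experiment.manifest.copy()
    manifest["path"] = paths
    _csv(manifest, out / "manifest.csv")
    _csv(experiment.calliper, out / "calliper.csv")
    _csv(experiment.extents, out / "extents.csv")
    return out


def load_experiment_dir(in_dir: str | Path) -> SyntheticExperiment:
    """Reload an experiment written by :func:`write_experiment`."""
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.csv"
    if not manifest_path.exists():
        raise PipelineStageError("extract", f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    signals = []
    for rec in manifest.itertuples(index=False):
        signals.append(
            read_signal_csv(
                in_dir / rec.path,
                plate_id=str(rec.plate_id),
                location_index=int(rec.location_index),
                impact_index=int(rec.impact_index),
                procedure=str(rec.procedure),
            )
        )
    calliper_path = in_dir / "calliper.csv"
    extents_path = in_dir / "extents.csv"
    calliper = pd.read_csv(calliper_path) if calliper_path.exists() else pd.DataFrame()
    extents = pd.read_csv(extents_path) if extents_path.exists() else pd.DataFrame()
    return SyntheticExperiment(
        signals=tuple(signals),
        manifest=manifest.drop(columns=["path"]),
        calliper=calliper,
        extents=extents,
    )
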