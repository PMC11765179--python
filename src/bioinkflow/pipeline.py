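"""End-to-end pipeline: generate -> fit rheology -> train -> evaluate -> optimize.

The pipeline mirrors the full workflow: regenerate the flow-curve
dataset from the canonical parameter sets, re-fit the Cross and
Herschel–Bulkley models per composition, train the three viscosity
surrogates, validate them by repeated holdout, and run both formulation
optimization scenarios against the structural-integrity window.

A single master seed deterministically derives per-stage seeds (stable
stage-name hashing), so any stage can be re-run in isolation and two
runs with the same config are byte-identical.  Every stage persists its
artifacts as CSV/JSON under ``<out>/<stage>/``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import datasets, rheology
from .optimize import SearchBounds, TargetWindow, optimize_formulation
from .surrogates import (
    log_target,
    make_surrogate_factory,
    model_from_dict,
    repeated_holdout,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "render_report"]

logger = logging.getLogger("bioinkflow.pipeline")

STAGES = ("generate", "fit_rheology", "train", "evaluate", "optimize")

_KNOWN_SURROGATES = ("poly", "tree", "forest")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "dataset": {
        "grid": {"min": 0.1, "max": 100.0, "n": 21, "spacing": "log"},
        "noise_sigma": 0.05,
    },
    "surrogates": [
        {"kind": "poly", "degree": 4},
        {"kind": "tree"},
        {"kind": "forest", "n_trees": 200},
    ],
    "validation": {"iterations": 100, "train_fraction": 0.8},
    "optimization": {
        "scenarios": ["free", "highshear"],
        "surrogate": "forest",
        "window": {"lower": 11.52, "upper": 13.12},
    },
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (round-trips through YAML)."""

    raw: dict

    @classmethod
    def default(cls, seed: int | None = None) -> "PipelineConfig":
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))
        if seed is not None:
            cfg["seed"] = seed
        return cls(cfg)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def __post_init__(self) -> None:
        cfg = self.raw
        if "seed" not in cfg:
            raise ValueError("config must set an explicit master seed")
        for spec in cfg.get("surrogates", []):
            if spec.get("kind") not in _KNOWN_SURROGATES:
                raise ValueError(
                    f"unknown surrogate kind {spec.get('kind')!r}; "
                    f"expected one of {_KNOWN_SURROGATES}"
                )
        for scen in cfg.get("optimization", {}).get("scenarios", []):
            if scen not in ("free", "highshear"):
                raise ValueError(f"unknown optimization scenario {scen!r}")
        frac = cfg.get("validation", {}).get("train_fraction", 0.8)
        if not (0 < frac < 1):
            raise ValueError("validation.train_fraction must be in (0, 1)")

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the master seed by name hashing."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)


@dataclass
class RunReport:
    config_hash: str
    out_dir: str
    stages: dict = field(default_factory=dict)  # name -> {status, artifacts, summary}

    def stage_ok(self, name: str) -> bool:
        return self.stages.get(name, {}).get("status") == "ok"

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "out_dir": self.out_dir, "stages": self.stages}


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute all stages in order, persisting every intermediate artifact.

    A failing stage is recorded as failed with its error message and all
    later stages are skipped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    report = RunReport(config_hash=config.config_hash(), out_dir=str(out))

    dataset = None
    trained: dict[str, object] = {}
    failed = False
    for stage in STAGES:
        if failed:
            report.stages[stage] = {"status": "skipped", "artifacts": [], "summary": {}}
            continue
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        try:
            _log(stage, "starting")
            if stage == "generate":
                dataset = _stage_generate(config, stage_dir, report)
            elif stage == "fit_rheology":
                _stage_fit_rheology(dataset, stage_dir, report)
            elif stage == "train":
                trained = _stage_train(config, dataset, stage_dir, report)
            elif stage == "evaluate":
                _stage_evaluate(config, dataset, stage_dir, report)
            elif stage == "optimize":
                _stage_optimize(config, dataset, trained, stage_dir, report)
            _log(stage, "done")
        except Exception as exc:  # fail fast, naming the stage
            _log(stage, f"FAILED: {exc}")
            report.stages[stage] = {
                "status": "failed", "error": str(exc), "artifacts": [], "summary": {},
            }
            failed = True
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    return report


def _stage_generate(config, stage_dir: Path, report: RunReport):
    ds_cfg = config.raw.get("dataset", {})
    grid = datasets.GridSpec(**ds_cfg.get("grid", {}))
    dataset = datasets.generate_dataset(
        grid=grid,
        noise_sigma=ds_cfg.get("noise_sigma", 0.05),
        seed=config.stage_seed("generate"),
    )
    path = stage_dir / "flow_curves.csv"
    datasets.write_dataset(dataset, path)
    report.stages["generate"] = {
        "status": "ok",
        "artifacts": [str(path)],
        "summary": {"n_rows": len(dataset), "n_compositions": len(dataset.compositions)},
    }
    return dataset


def _stage_fit_rheology(dataset, stage_dir: Path, report: RunReport) -> None:
    fits = {}
    for label in dataset.compositions:
        sub = dataset.frame[dataset.frame["composition"] == label]
        gd = sub["shear_rate"].to_numpy()
        cross = rheology.fit_cross(np.column_stack([gd, sub["viscosity_mPas"]]))
        hb = rheology.fit_herschel(np.column_stack([gd, sub["shear_stress_Pa"]]))
        cp, hp = cross.params, hb.params
        fits[label] = {
            "cross": {
                "eta_inf_mPas": cp.eta_inf, "eta_0_mPas": cp.eta_0,
                "t_s": cp.t, "m": cp.m, "adj_r2": cross.adj_r2,
                "converged": cross.converged,
            },
            "herschel": {
                "tau_0_Pa": hp.tau_0, "K_mPasn": hp.K, "n": hp.n,
                "adj_r2": hb.adj_r2, "converged": hb.converged,
            },
        }
    path = stage_dir / "rheology_fits.json"
    path.write_text(json.dumps(fits, indent=2) + "\n")
    report.stages["fit_rheology"] = {
        "status": "ok", "artifacts": [str(path)],
        "summary": {"n_cross_fits": len(fits), "n_herschel_fits": len(fits)},
    }


def _stage_train(config, dataset, stage_dir: Path, report: RunReport) -> dict:
    X, y = log_target(dataset)
    seed = config.stage_seed("train")
    trained = {}
    artifacts = []
    for spec in config.raw.get("surrogates", []):
        spec = dict(spec)
        kind = spec.pop("kind")
        factory = make_surrogate_factory(kind, **spec)
        model = factory(X, y, seed)
        trained[kind] = model
        path = stage_dir / f"{kind}.json"
        path.write_text(json.dumps(model.to_dict()) + "\n")
        artifacts.append(str(path))
    report.stages["train"] = {
        "status": "ok", "artifacts": artifacts,
        "summary": {"models": list(trained)},
    }
    return trained


def _stage_evaluate(config, dataset, stage_dir: Path, report: RunReport) -> None:
    X, y = log_target(dataset)
    val = config.raw.get("validation", {})
    seed = config.stage_seed("evaluate")
    metrics = {}
    artifacts = []
    for spec in config.raw.get("surrogates", []):
        spec = dict(spec)
        kind = spec.pop("kind")
        rep = repeated_holdout(
            X, y, make_surrogate_factory(kind, **spec),
            iterations=val.get("iterations", 100),
            train_fraction=val.get("train_fraction", 0.8),
            seed=seed,
        )
        metrics[kind] = {"model": kind, **rep.to_dict()}
        path = stage_dir / f"{kind}_metrics.json"
        path.write_text(json.dumps(metrics[kind], indent=2) + "\n")
        artifacts.append(str(path))
    report.stages["evaluate"] = {
        "status": "ok", "artifacts": artifacts,
        "summary": {
            kind: {"r2_mean": m["r2_mean"], "mae_mean": m["mae_mean"]}
            for kind, m in metrics.items()
        },
    }


def _stage_optimize(config, dataset, trained, stage_dir: Path, report: RunReport) -> None:
    opt_cfg = config.raw.get("optimization", {})
    kind = opt_cfg.get("surrogate", "forest")
    if kind not in trained:
        raise ValueError(f"optimization surrogate {kind!r} was not trained")
    window_cfg = opt_cfg.get("window", {})
    window = TargetWindow(
        lower=window_cfg.get("lower", 11.52), upper=window_cfg.get("upper", 13.12)
    )
    seed = config.stage_seed("optimize")
    results = {}
    artifacts = []
    for scenario in opt_cfg.get("scenarios", ["free", "highshear"]):
        bounds = SearchBounds.from_dataset(dataset)
        res = optimize_formulation(
            trained[kind], bounds, scenario=scenario, window=window, seed=seed,
            **opt_cfg.get("de", {}),
        )
        results[scenario] = res.to_dict()
        path = stage_dir / f"{scenario}.json"
        path.write_text(json.dumps(results[scenario], indent=2) + "\n")
        artifacts.append(str(path))
    report.stages["optimize"] = {
        "status": "ok", "artifacts": artifacts,
        "summary": {
            s: {"ln_viscosity_pred": r["ln_viscosity_pred"], "in_window": r["in_window"]}
            for s, r in results.items()
        },
    }


def load_artifact(report: RunReport, stage: str, name: str):
    """Load a persisted JSON artifact from a completed run."""
    for art in report.stages.get(stage, {}).get("artifacts", []):
        if Path(art).name == name:
            with open(art) as fh:
                return json.load(fh)
    raise FileNotFoundError(f"no artifact {name!r} in stage {stage!r}")


def render_report(report: RunReport) -> str:
    """Human-readable summary of a pipeline run.

    Tabulates per-composition rheology fits, the surrogate comparison
    (mean R² / MAE over holdout iterations) and the optimization
    outcomes; incomplete runs produce a partial report with warnings.
    """
    lines = [f"bioinkflow pipeline run (config {report.config_hash})", ""]
    warnings = [
        f"WARNING: stage {s!r} {info['status']}"
        + (f" ({info.get('error')})" if info.get("error") else "")
        for s, info in report.stages.items()
        if info.get("status") != "ok"
    ]

    if report.stage_ok("fit_rheology"):
        fits = json.load(open(report.stages["fit_rheology"]["artifacts"][0]))
        lines.append("Rheology fits (Cross | Herschel-Bulkley):")
        hdr = (
            f"{'composition':<16}{'eta_inf':>10}{'eta_0':>12}{'t':>8}{'m':>7}"
            f"{'AdjR2':>7} |{'tau_0':>8}{'K':>9}{'n':>6}{'AdjR2':>7}"
        )
        lines.append(hdr)
        for label, f in fits.items():
            c, h = f["cross"], f["herschel"]
            lines.append(
                f"{label:<16}{c['eta_inf_mPas']:>10.0f}{c['eta_0_mPas']:>12.0f}"
                f"{c['t_s']:>8.2f}{c['m']:>7.2f}{c['adj_r2']:>7.3f} |"
                f"{h['tau_0_Pa']:>8.2f}{h['K_mPasn']:>9.1f}{h['n']:>6.2f}"
                f"{h['adj_r2']:>7.3f}"
            )
        lines.append("")

    if report.stage_ok("evaluate"):
        lines.append("Surrogate comparison (holdout means, ln-viscosity units):")
        lines.append(f"{'model':<10}{'R2':>8}{'MAE':>8}")
        summary = report.stages["evaluate"]["summary"]
        for kind, m in summary.items():
            lines.append(f"{kind:<10}{m['r2_mean']:>8.3f}{m['mae_mean']:>8.3f}")
        order = sorted(summary, key=lambda k: summary[k]["r2_mean"])
        lines.append("R2 ordering: " + " <= ".join(order))
        lines.append("")

    if report.stage_ok("optimize"):
        lines.append("Optimization scenarios:")
        for scen, m in report.stages["optimize"]["summary"].items():
            flag = "in window" if m["in_window"] else "OUT OF WINDOW"
            lines.append(
                f"  {scen:<10} ln(viscosity) = {m['ln_viscosity_pred']:.3f}  ({flag})"
            )
        lines.append("")
    else:
        warnings.append("WARNING: optimization scenarios missing from report")

    return "\n".join(lines + warnings)
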