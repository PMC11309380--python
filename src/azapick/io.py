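"""Readers, writers, configuration and run manifests.

All tables are comma-separated UTF-8 with a header row; patterns and
reports are JSON; configs are YAML. Percentages are serialized on the
0–100 scale rounded to 2 decimals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossval import ExperimentConfig, ExperimentResult
from .errors import ConfigError
from .patterns import MiningResult, Pattern
from .simulate import MetaboliteSpec, PlantedRule, PredictorSpec


def read_table(path) -> pd.DataFrame:
    """Read a package CSV, with parse errors naming file and field."""
    try:
        return pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message formatting
        raise ConfigError(f"cannot parse {path}: {exc}") from exc


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_patterns_json(mining: MiningResult, path) -> None:
    """Mined patterns with per-shuffle support and sensitivity (2-decimal %)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "n_shuffles": mining.n_shuffles,
        "model_ids": list(mining.model_ids),
        "patterns": mining.to_records(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_patterns_json(path) -> list[Pattern]:
    payload = json.loads(Path(path).read_text())
    return [
        Pattern(tuple(p["members"]), tuple(p["assigned"]), p["implied_A_class"])
        for p in payload["patterns"]
    ]


def write_curve_csv(curve: pd.DataFrame, path) -> None:
    out = curve.copy()
    for c in out.columns:
        if c.startswith(("mean_sensitivity", "sd")):
            out[c] = out[c].round(2)
    write_table(out, path)


def write_aggregate_json(result: ExperimentResult, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _round(o):
        if isinstance(o, dict):
            return {k: _round(v) for k, v in o.items()}
        if isinstance(o, float):
            return round(o, 4)
        return o

    Path(path).write_text(json.dumps(_round(result.aggregate_json()), indent=1))


# -- configuration -----------------------------------------------------------

def config_to_dict(config: ExperimentConfig) -> dict:
    return {
        "n_samples": config.n_samples,
        "n_shuffles": config.n_shuffles,
        "ratios": list(config.ratios),
        "correlation_rho": config.correlation_rho,
        "min_support_shuffles": config.min_support_shuffles,
        "stratify_splits": config.stratify_splits,
        "holdout": config.holdout,
        "metabolites": [
            {"name": s.name, "min": s.min_conc, "max": s.max_conc, "mean": s.mean_conc}
            for s in config.metabolite_specs
        ],
        "predictors": [
            {"model_id": p.model_id, "sens_low": p.sens_low, "sens_high": p.sens_high}
            for p in config.predictor_specs
        ],
        "planted_rules": [
            {
                "members": list(r.members),
                "assigned": list(r.assigned),
                "implied_class": r.implied_class,
                "penetrance": r.penetrance,
                "coverage": r.coverage,
            }
            for r in config.planted_rules
        ],
    }


def config_from_dict(d: dict) -> ExperimentConfig:
    try:
        cfg = ExperimentConfig(
            n_samples=int(d.get("n_samples", 1045)),
            n_shuffles=int(d.get("n_shuffles", 10)),
            ratios=tuple(d.get("ratios", (0.8, 0.1, 0.1))),
            correlation_rho=float(d.get("correlation_rho", 0.3)),
            min_support_shuffles=int(d.get("min_support_shuffles", d.get("n_shuffles", 10))),
            stratify_splits=bool(d.get("stratify_splits", False)),
            holdout=bool(d.get("holdout", False)),
        )
        if "metabolites" in d:
            cfg.metabolite_specs = [
                MetaboliteSpec(s["name"], float(s["min"]), float(s["max"]), float(s["mean"]))
                for s in d["metabolites"]
            ]
        if "predictors" in d:
            cfg.predictor_specs = [
                PredictorSpec(p["model_id"], float(p["sens_low"]), float(p["sens_high"]))
                for p in d["predictors"]
            ]
        if "planted_rules" in d:
            cfg.planted_rules = [
                PlantedRule(
                    tuple(r["members"]), tuple(r["assigned"]), r["implied_class"],
                    float(r.get("penetrance", 1.0)), float(r.get("coverage", 1.0)),
                )
                for r in d["planted_rules"]
            ]
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed experiment config: {exc}") from exc
    cfg.validate()
    return cfg


def load_config(path) -> ExperimentConfig:
    try:
        d = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse YAML config {path}: {exc}") from exc
    return config_from_dict(d)


def save_config(config: ExperimentConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# -- run manifest ------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record written next to every CLI run's outputs."""

    config_hash: str
    seed: int
    version: str = __version__
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    timestamp: str = ""

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        d = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "inputs": [str(p) for p in self.inputs],
            "outputs": [str(p) for p in self.outputs],
            "timestamp": self.timestamp or datetime.now(timezone.utc).isoformat(),
        }
        Path(path).write_text(json.dumps(d, indent=1))
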