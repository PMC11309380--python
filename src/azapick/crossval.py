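"""Ten-shuffle experiment orchestration.

"Cross-validation" here follows the source protocol: ten *independent*
random 80:10:10 splits into train/validation/test (not disjoint folds).
For each shuffle the surrogate predictors are re-simulated (standing in
for retraining the image models), the single-analyte fruit-A model is
scored on the shuffle's test subset, complete-specificity patterns are
mined across all test subsets, and boosted predictions are scored. Means
± sample SD (ddof = 1) aggregate the per-shuffle values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .labeling import assign_classes, make_splits, mean_thresholds
from .metrics import MetricsReport, evaluate_classes
from .patterns import MiningResult, encode_predictions, mine_patterns, sensitivity_curve
from .simulate import (
    MetaboliteSpec,
    PlantedRule,
    PredictorSpec,
    default_correlation,
    default_metabolite_specs,
    default_predictor_specs,
    simulate_concentrations,
    simulate_predictions,
)


@dataclass
class ExperimentConfig:
    """Knobs of the synthetic ten-shuffle experiment.

    Defaults reproduce the study conditions: n = 1045 trees, ten random
    80:10:10 shuffles, published concentration ranges/means, predictor
    operating points near the reported test metrics, and an exchangeable
    Spearman correlation of 0.3 among metabolites.
    """

    n_samples: int = 1045
    n_shuffles: int = 10
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    correlation_rho: float = 0.3
    metabolite_specs: list[MetaboliteSpec] = field(default_factory=default_metabolite_specs)
    predictor_specs: list[PredictorSpec] = field(default_factory=default_predictor_specs)
    planted_rules: list[PlantedRule] = field(default_factory=list)
    min_support_shuffles: int = 10
    stratify_splits: bool = False
    holdout: bool = False   # mine on shuffles 0..S-2, score boosting on the last only

    def validate(self) -> None:
        if self.n_samples < 10:
            raise ConfigError(f"n_samples={self.n_samples} too small for 80:10:10 splits")
        if self.n_shuffles < 1:
            raise ConfigError("need at least one shuffle")
        if not 1 <= self.min_support_shuffles <= self.n_shuffles:
            raise ConfigError(
                f"min_support_shuffles={self.min_support_shuffles} outside 1..{self.n_shuffles}"
            )
        if not -1.0 / (len(self.metabolite_specs) - 1) < self.correlation_rho < 1.0:
            raise ConfigError(f"correlation_rho={self.correlation_rho} not a valid exchangeable correlation")
        if self.holdout and self.n_shuffles < 2:
            raise ConfigError("holdout mode needs at least two shuffles")


@dataclass
class ShuffleResult:
    """Per-shuffle test-set scores."""

    shuffle_id: int
    single: MetricsReport
    boosted: MetricsReport | None      # scored on decided (non-abstain) samples
    n_abstain: int
    n_conflict: int
    coverage_sensitivity: dict        # % of each true class matched by the pattern union


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    seed: int
    records: pd.DataFrame
    labels: pd.DataFrame
    splits: pd.DataFrame
    thresholds: dict
    shuffles: list[ShuffleResult]
    mining: MiningResult
    curve: pd.DataFrame
    aggregate: dict

    def aggregate_json(self) -> dict:
        return {
            "seed": self.seed,
            "n_samples": self.config.n_samples,
            "n_shuffles": self.config.n_shuffles,
            "min_support_shuffles": self.config.min_support_shuffles,
            "sd_definition": "sample (ddof=1)",
            "metrics": self.aggregate,
        }


def _mean_sd(values) -> dict:
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    if vals.size == 0:
        return {"mean": None, "sd": None, "n": 0}
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return {"mean": float(np.mean(vals)), "sd": sd, "n": int(vals.size)}


def run_experiment(config: ExperimentConfig | None = None, seed: int = 0) -> ExperimentResult:
    """Run the full synthetic pipeline end to end, deterministically under ``seed``."""
    config = config or ExperimentConfig()
    config.validate()
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(2 + config.n_shuffles)

    records = simulate_concentrations(
        config.n_samples,
        config.metabolite_specs,
        default_correlation(config.correlation_rho),
        np.random.default_rng(child[0]),
    )
    thresholds = mean_thresholds(records)
    labels = assign_classes(records, thresholds)
    splits = make_splits(
        records["sample_id"],
        config.ratios,
        config.n_shuffles,
        np.random.default_rng(child[1]),
        stratify_by=labels["A"] if config.stratify_splits else None,
    )

    test_tables = []
    for s in range(config.n_shuffles):
        preds = simulate_predictions(
            records, labels, config.predictor_specs, config.planted_rules,
            np.random.default_rng(child[2 + s]),
        )
        ids = splits.query("shuffle_id == @s and subset == 'test'")["sample_id"]
        test_tables.append(preds[preds["sample_id"].isin(set(ids))].reset_index(drop=True))

    mine_on = test_tables[:-1] if config.holdout else test_tables
    mining = mine_patterns(mine_on, min_support_shuffles=1)
    curve = sensitivity_curve(mining)

    score_range = ([config.n_shuffles - 1] if config.holdout else range(config.n_shuffles))
    shuffles = []
    for s in range(config.n_shuffles):
        table = test_tables[s]
        truth = table["true_A"].to_numpy()
        single = evaluate_classes(table["pred_A_f"].to_numpy(), truth)
        if s not in score_range:
            shuffles.append(ShuffleResult(s, single, None, 0, 0, {}))
            continue
        bits = encode_predictions(table)
        boosted_calls = mining.boost_bits(bits, config.min_support_shuffles)
        decided = (boosted_calls == "low") | (boosted_calls == "high")
        boosted = (
            evaluate_classes(boosted_calls[decided], truth[decided]) if decided.any() else None
        )
        coverage = {}
        for key, cls in (("l", "low"), ("h", "high")):
            in_cls = truth == cls
            hit = decided & (boosted_calls == cls) & in_cls
            coverage[key] = 100.0 * hit.sum() / in_cls.sum() if in_cls.any() else None
        shuffles.append(ShuffleResult(
            s, single, boosted,
            n_abstain=int((boosted_calls == "abstain").sum()),
            n_conflict=int((boosted_calls == "conflict").sum()),
            coverage_sensitivity=coverage,
        ))

    scored = [r for r in shuffles if r.boosted is not None or r.coverage_sensitivity]
    aggregate = {}
    for key in ("l", "h"):
        aggregate[f"single_sensitivity_{key}"] = _mean_sd(r.single.sensitivity[key] for r in shuffles)
        aggregate[f"single_specificity_{key}"] = _mean_sd(r.single.specificity[key] for r in shuffles)
        aggregate[f"boosted_sensitivity_{key}"] = _mean_sd(
            r.coverage_sensitivity.get(key) for r in scored
        )
        aggregate[f"boosted_specificity_{key}"] = _mean_sd(
            r.boosted.specificity[key] if r.boosted else None for r in scored
        )
        aggregate[f"cv_error_{key}"] = _mean_sd(
            1.0 - r.coverage_sensitivity[key] / 100.0
            for r in scored if r.coverage_sensitivity.get(key) is not None
        )
    aggregate["n_mined_patterns"] = len(mining.patterns)
    aggregate["n_abstain_total"] = int(sum(r.n_abstain for r in scored))
    aggregate["n_conflict_total"] = int(sum(r.n_conflict for r in scored))

    return ExperimentResult(
        config=config, seed=seed, records=records, labels=labels, splits=splits,
        thresholds=thresholds, shuffles=shuffles, mining=mining, curve=curve,
        aggregate=aggregate,
    )
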