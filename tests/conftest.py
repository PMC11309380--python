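import numpy as np
import pandas as pd
import pytest

from azapick import (
    MODEL_IDS,
    PlantedRule,
    assign_classes,
    default_metabolite_specs,
    mean_thresholds,
    simulate_concentrations,
    simulate_predictions,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20241045)


@pytest.fixture
def records():
    """Small concentration table with known structure."""
    return simulate_concentrations(200, seed=7)


@pytest.fixture
def labels(records):
    return assign_classes(records, mean_thresholds(records))


@pytest.fixture
def perfect_table(records, labels):
    """Predictions from perfect surrogates: every model calls its truth."""
    from azapick import PredictorSpec

    specs = [PredictorSpec(m, 1.0, 1.0) for m in MODEL_IDS]
    return simulate_predictions(records, labels, specs, seed=11)


def make_table(pred_rows, true_a, model_ids):
    """Build a prediction table from per-row class lists."""
    data = {"sample_id": [f"s{i}" for i in range(len(pred_rows))], "true_A": list(true_a)}
    for j, m in enumerate(model_ids):
        data[f"pred_{m}"] = [r[j] for r in pred_rows]
    return pd.DataFrame(data)


def random_tables(rng, model_ids, n_shuffles, n_rows):
    """Random per-shuffle test tables for oracle comparisons."""
    tables = []
    for _ in range(n_shuffles):
        rows = [
            ["high" if rng.random() < 0.5 else "low" for _ in model_ids]
            for _ in range(n_rows)
        ]
        truth = ["high" if rng.random() < 0.5 else "low" for _ in range(n_rows)]
        tables.append(make_table(rows, truth, model_ids))
    return tables


@pytest.fixture
def planted_rules():
    return [
        PlantedRule(("D_f", "S_f"), ("high", "high"), "high"),
        PlantedRule(("D_f", "S_f"), ("low", "low"), "low"),
    ]
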