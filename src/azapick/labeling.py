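"""Mean-threshold class formation and random train/validation/test splits."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .simulate import METABOLITES

logger = logging.getLogger(__name__)

SUBSETS = ("train", "validation", "test")


def mean_thresholds(records: pd.DataFrame) -> dict[str, float]:
    """Per-metabolite empirical means, the class thresholds used throughout."""
    return {m: float(records[m].mean()) for m in METABOLITES}


def assign_classes(records: pd.DataFrame, thresholds: dict[str, float]) -> pd.DataFrame:
    """Binarise concentrations: > threshold is *high*, otherwise *low*.

    A concentration exactly equal to the threshold is labelled *low* (the
    tie rule; ties are measure-zero for continuous assays but must be
    deterministic). Samples with any missing concentration are dropped
    with a logged warning, as is a threshold outside the observed range
    (which can only produce a single class).
    """
    for m in METABOLITES:
        if m not in thresholds:
            raise InvalidArgumentError(f"missing threshold for metabolite {m}")
        lo, hi = records[m].min(), records[m].max()
        if not (lo <= thresholds[m] <= hi):
            logger.warning(
                "threshold %s for %s outside observed range [%s, %s]; "
                "all samples will fall in one class", thresholds[m], m, lo, hi,
            )
    bad = records[list(METABOLITES)].isna().any(axis=1)
    if bad.any():
        logger.warning(
            "excluding %d sample(s) with missing concentrations: %s",
            int(bad.sum()),
            ", ".join(records.loc[bad, "sample_id"].astype(str)),
        )
    kept = records.loc[~bad]
    out = pd.DataFrame({"sample_id": kept["sample_id"].to_numpy()})
    for m in METABOLITES:
        out[m] = np.where(kept[m].to_numpy() > thresholds[m], "high", "low")
    return out


def split_sizes(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    """Subset sizes: floor(n*ratio) for validation and test, remainder to train."""
    n_val = int(np.floor(n * ratios[1]))
    n_test = int(np.floor(n * ratios[2]))
    return n - n_val - n_test, n_val, n_test


def make_splits(
    samples: list[str] | np.ndarray,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    n_shuffles: int = 10,
    seed: int | np.random.Generator = 0,
    stratify_by: pd.Series | None = None,
) -> pd.DataFrame:
    """Assign samples to train/validation/test for each random shuffle.

    Each shuffle is an independent uniform permutation (simple random
    splitting, matching the unequal class counts a real survey shows
    across shuffles). Pass ``stratify_by`` (a class per sample) to split
    within strata instead.

    Returns a DataFrame with columns ``sample_id, shuffle_id, subset``.
    """
    samples = list(samples)
    n = len(samples)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise InvalidArgumentError(f"ratios must sum to 1, got {ratios}")
    if n_shuffles < 1:
        raise InvalidArgumentError(f"need n_shuffles >= 1, got {n_shuffles}")
    n_train, n_val, n_test = split_sizes(n, ratios)
    if min(n_train, n_val, n_test) < 1:
        raise InvalidArgumentError(
            f"n={n} too small for three nonempty subsets at ratios {ratios}"
        )
    rng = np.random.default_rng(seed)

    frames = []
    for shuffle_id in range(n_shuffles):
        if stratify_by is not None:
            subset = np.empty(n, dtype=object)
            strata = pd.Series(list(stratify_by), index=range(n))
            for _, idx in strata.groupby(strata).groups.items():
                idx = rng.permutation(np.fromiter(idx, dtype=int))
                k = len(idx)
                kt, kv, _ = split_sizes(k, ratios)
                subset[idx[:kt]] = "train"
                subset[idx[kt:kt + kv]] = "validation"
                subset[idx[kt + kv:]] = "test"
        else:
            perm = rng.permutation(n)
            subset = np.empty(n, dtype=object)
            subset[perm[:n_train]] = "train"
            subset[perm[n_train:n_train + n_val]] = "validation"
            subset[perm[n_train + n_val:]] = "test"
        frames.append(
            pd.DataFrame(
                {"sample_id": samples, "shuffle_id": shuffle_id, "subset": subset}
            )
        )
    return pd.concat(frames, ignore_index=True)
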