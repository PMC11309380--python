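"""Classification metrics: precision, recall, F1, sensitivity/specificity, CV error.

Percentages are reported on the 0–100 scale; proportions on 0–1. A metric
whose denominator is empty is *undefined* and reported as ``None`` (never
silently zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 tabulation with respect to a designated positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InvalidArgumentError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None


def confusion(preds, truths, positive: str) -> ConfusionCounts:
    """Tabulate predictions against truths with ``positive`` as the positive class."""
    preds = np.asarray(preds)
    truths = np.asarray(truths)
    if preds.shape != truths.shape:
        raise InvalidArgumentError(
            f"length mismatch: {preds.shape} predictions vs {truths.shape} truths"
        )
    p = preds == positive
    t = truths == positive
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall, 2PR/(P+R).

    Defined as 0 when both arguments are 0 (with a logged note), the
    conventional limit for a degenerate classifier.
    """
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise InvalidArgumentError(f"P={precision}, R={recall} must lie in [0, 1]")
    if precision == 0.0 and recall == 0.0:
        logger.info("F1 undefined at P=R=0; reporting 0")
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def class_sensitivity_specificity(counts: ConfusionCounts) -> tuple[float | None, float | None]:
    """(sensitivity %, specificity %) of the positive class.

    sensitivity = 100·tp/(tp+fn); specificity = 100·tn/(tn+fp). Either is
    ``None`` when its class is empty.
    """
    sens = 100.0 * counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    spec = 100.0 * counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    return sens, spec


def cv_error(per_shuffle_errors) -> tuple[float, float]:
    """Cross-validation error: mean of per-shuffle errors, with sample SD.

    SD uses the n−1 denominator (0.0 for a single shuffle).
    """
    errs = np.asarray(list(per_shuffle_errors), dtype=float)
    if errs.size == 0:
        raise InvalidArgumentError("no per-shuffle errors given")
    if np.any((errs < 0) | (errs > 1)):
        raise InvalidArgumentError("per-shuffle errors must lie in [0, 1]")
    sd = float(np.std(errs, ddof=1)) if errs.size > 1 else 0.0
    return float(np.mean(errs)), sd


@dataclass(frozen=True)
class MetricsReport:
    """P/R/F1 per class plus their macro average, and per-class sensitivity/specificity.

    ``precision``/``recall``/``f1`` map ``"l"``, ``"h"`` and ``"a"``
    (macro average of the two classes) to proportions; ``sensitivity`` and
    ``specificity`` map ``"l"``/``"h"`` to percentages. ``None`` marks an
    undefined entry.
    """

    precision: dict
    recall: dict
    f1: dict
    sensitivity: dict
    specificity: dict
    n_scored: int

    def as_flat_dict(self) -> dict:
        out = {"n_scored": self.n_scored}
        for name in ("precision", "recall", "f1"):
            for k, v in getattr(self, name).items():
                out[f"{name}_{k}"] = v
        for name in ("sensitivity", "specificity"):
            for k, v in getattr(self, name).items():
                out[f"{name}_{k}"] = v
        return out


def _macro(lo: float | None, hi: float | None) -> float | None:
    if lo is None or hi is None:
        return None
    return (lo + hi) / 2.0


def evaluate_classes(preds, truths) -> MetricsReport:
    """Full per-class and macro report for binary low/high predictions."""
    per = {}
    for key, positive in (("l", "low"), ("h", "high")):
        c = confusion(preds, truths, positive)
        p, r = c.precision(), c.recall()
        f = f1_score(p, r) if (p is not None and r is not None and (p or r)) else None
        sens, spec = class_sensitivity_specificity(c)
        per[key] = (p, r, f, sens, spec)
    (pl, rl, fl, sl, cl), (ph, rh, fh, sh, ch) = per["l"], per["h"]
    return MetricsReport(
        precision={"a": _macro(pl, ph), "l": pl, "h": ph},
        recall={"a": _macro(rl, rh), "l": rl, "h": rh},
        f1={"a": _macro(fl, fh), "l": fl, "h": fh},
        sensitivity={"l": sl, "h": sh},
        specificity={"l": cl, "h": ch},
        n_scored=len(np.asarray(preds)),
    )
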