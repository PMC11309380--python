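"""Multi-analyte pattern mining with complete specificity.

The single-analyte route predicts the fruit-azadirachtin (fruit-A) class
from the fruit-A model alone. The multi-analyte route mines, across the
test subsets of all dataset shuffles, every class-assignment tuple over the
ten metabolite models — pairs, 3-tuples, …, up to the full 10-tuple, 3¹⁰−1
= 59 048 patterns in all — and keeps those with *complete specificity*:
in every shuffle where the tuple matches at least one test sample, the
matched samples all share one true fruit-A class, and that class is the
same in every such shuffle. Retained patterns are ranked by *shuffle
support* (how many shuffles they matched in) and used to boost the fruit-A
call, with the final horticultural decision reduced to Pick / Do not Pick.

Patterns are represented as bitmasks over the ten models (bit set = member;
assignment bit set = *high*), which lets a whole shuffle be matched against
all 59 048 patterns with two vectorised integer operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .simulate import MODEL_IDS

BOOST_OUTCOMES = ("low", "high", "abstain", "conflict")


@dataclass(frozen=True)
class Pattern:
    """A subset of models with one assigned class per member.

    Identity is ``(members, assigned)``; ``implied_A_class`` is set only
    once mining has established the direction the pattern predicts.
    """

    members: tuple[str, ...]
    assigned: tuple[str, ...]
    implied_A_class: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise InvalidArgumentError("pattern needs at least one member")
        if len(self.assigned) != len(self.members):
            raise InvalidArgumentError("assigned classes must align with members")

    def assignment(self) -> dict[str, str]:
        return dict(zip(self.members, self.assigned))

    def name(self) -> str:
        """Compact tuple notation, e.g. ``D_f:high+S_f:high``."""
        return "+".join(f"{m}:{c}" for m, c in zip(self.members, self.assigned))

    def matches(self, row: Mapping) -> bool:
        """True iff every member model's predicted class equals its assigned class.

        ``row`` maps model ids (or ``pred_<model_id>`` column names) to
        ``"low"``/``"high"``.
        """
        vals = []
        for m in self.members:
            if m in row:
                vals.append(row[m])
            elif f"pred_{m}" in row:
                vals.append(row[f"pred_{m}"])
            else:
                raise InvalidArgumentError(f"row lacks a prediction for {m}")
        return all(v == c for v, c in zip(vals, self.assigned))


def _pattern_arrays(model_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Bitmask (members) and assignment-bit arrays for all 3^k − 1 patterns.

    Subsets are enumerated in increasing mask order over the model bit
    order, assignments in binary order with low = 0 — a fixed order so
    outputs are diffable.
    """
    k = len(model_ids)
    masks, abits = [], []
    for mask in range(1, 1 << k):
        bits = [b for b in range(k) if mask >> b & 1]
        for assign in range(1 << len(bits)):
            a = 0
            for j, b in enumerate(bits):
                if assign >> j & 1:
                    a |= 1 << b
            masks.append(mask)
            abits.append(a)
    return np.asarray(masks, dtype=np.int64), np.asarray(abits, dtype=np.int64)


def _pattern_from_bits(mask: int, abit: int, model_ids: Sequence[str],
                       implied: str | None = None) -> Pattern:
    members = tuple(m for b, m in enumerate(model_ids) if mask >> b & 1)
    assigned = tuple(
        "high" if abit >> b & 1 else "low"
        for b, m in enumerate(model_ids) if mask >> b & 1
    )
    return Pattern(members, assigned, implied)


def enumerate_patterns(model_ids: Sequence[str] = MODEL_IDS) -> list[Pattern]:
    """Every (nonempty subset, class assignment) pair — 3^k − 1 patterns."""
    model_ids = tuple(model_ids)
    if len(set(model_ids)) != len(model_ids):
        raise InvalidArgumentError(f"duplicate model ids in {model_ids}")
    masks, abits = _pattern_arrays(model_ids)
    return [_pattern_from_bits(int(m), int(a), model_ids) for m, a in zip(masks, abits)]


def match(pattern: Pattern, row: Mapping) -> bool:
    """Functional alias for :meth:`Pattern.matches`."""
    return pattern.matches(row)


def encode_predictions(table: pd.DataFrame, model_ids: Sequence[str] = MODEL_IDS) -> np.ndarray:
    """Pack each row's predictions into an integer, bit b set iff model b called *high*."""
    bits = np.zeros(len(table), dtype=np.int64)
    for b, m in enumerate(model_ids):
        col = f"pred_{m}" if f"pred_{m}" in table.columns else m
        if col not in table.columns:
            raise InvalidArgumentError(f"prediction table lacks a column for {m}")
        bits |= (table[col].to_numpy() == "high").astype(np.int64) << b
    return bits


@dataclass
class MiningResult:
    """Patterns surviving the complete-specificity screen, with bookkeeping.

    ``evaluations`` holds one row per (pattern, shuffle) with the matched
    counts by true fruit-A class and the per-shuffle sensitivity
    (percentage of that shuffle's true implied-class test samples the
    pattern matched; NaN where the pattern matched nothing).
    """

    patterns: list[Pattern]
    support: np.ndarray
    model_ids: tuple[str, ...]
    masks: np.ndarray
    abits: np.ndarray
    implied: np.ndarray            # "low"/"high" per mined pattern
    n_matched_low: np.ndarray      # (n_patterns, n_shuffles)
    n_matched_high: np.ndarray
    totals_low: np.ndarray         # true-class test totals per shuffle
    totals_high: np.ndarray
    row_bits: list[np.ndarray] = field(repr=False)
    true_a: list[np.ndarray] = field(repr=False)

    @property
    def n_shuffles(self) -> int:
        return len(self.totals_low)

    @property
    def evaluations(self) -> pd.DataFrame:
        rows = []
        for i, pat in enumerate(self.patterns):
            totals = self.totals_low if self.implied[i] == "low" else self.totals_high
            matched = (self.n_matched_low[i] if self.implied[i] == "low"
                       else self.n_matched_high[i])
            for s in range(self.n_shuffles):
                n_any = self.n_matched_low[i, s] + self.n_matched_high[i, s]
                rows.append({
                    "pattern": pat.name(),
                    "implied_A_class": self.implied[i],
                    "shuffle_id": s,
                    "n_matched_low": int(self.n_matched_low[i, s]),
                    "n_matched_high": int(self.n_matched_high[i, s]),
                    "sensitivity": (100.0 * matched[s] / totals[s]) if n_any else np.nan,
                })
        return pd.DataFrame(rows)

    def match_matrix(self, shuffle_id: int) -> np.ndarray:
        """Boolean (n_patterns, n_samples) match indicator for one shuffle."""
        rb = self.row_bits[shuffle_id]
        return (rb[None, :] & self.masks[:, None]) == self.abits[:, None]

    def boost_bits(self, row_bits: np.ndarray, min_support: int = 1) -> np.ndarray:
        """Vectorised :func:`boost_predictions` over packed prediction rows."""
        keep = self.support >= min_support
        out = np.full(len(row_bits), "abstain", dtype=object)
        if not keep.any():
            return out
        m = (row_bits[None, :] & self.masks[keep, None]) == self.abits[keep, None]
        imp = self.implied[keep]
        low_any = m[imp == "low"].any(axis=0) if (imp == "low").any() else np.zeros(len(row_bits), bool)
        high_any = m[imp == "high"].any(axis=0) if (imp == "high").any() else np.zeros(len(row_bits), bool)
        out[low_any & ~high_any] = "low"
        out[high_any & ~low_any] = "high"
        out[low_any & high_any] = "conflict"
        return out

    def filtered(self, min_support: int) -> "MiningResult":
        """View restricted to patterns with support >= ``min_support``."""
        keep = self.support >= min_support
        idx = np.flatnonzero(keep)
        return MiningResult(
            patterns=[self.patterns[i] for i in idx],
            support=self.support[keep],
            model_ids=self.model_ids,
            masks=self.masks[keep],
            abits=self.abits[keep],
            implied=self.implied[keep],
            n_matched_low=self.n_matched_low[keep],
            n_matched_high=self.n_matched_high[keep],
            totals_low=self.totals_low,
            totals_high=self.totals_high,
            row_bits=self.row_bits,
            true_a=self.true_a,
        )

    def to_records(self) -> list[dict]:
        """JSON-ready dump: members, assignments, implied class, per-shuffle stats."""
        recs = []
        for i, pat in enumerate(self.patterns):
            totals = self.totals_low if self.implied[i] == "low" else self.totals_high
            matched = (self.n_matched_low[i] if self.implied[i] == "low"
                       else self.n_matched_high[i])
            per_shuffle = []
            for s in range(self.n_shuffles):
                n_any = int(self.n_matched_low[i, s] + self.n_matched_high[i, s])
                per_shuffle.append({
                    "shuffle_id": s,
                    "n_matched_low": int(self.n_matched_low[i, s]),
                    "n_matched_high": int(self.n_matched_high[i, s]),
                    "sensitivity": round(100.0 * matched[s] / totals[s], 2) if n_any else None,
                })
            recs.append({
                "members": list(pat.members),
                "assigned": list(pat.assigned),
                "implied_A_class": str(self.implied[i]),
                "support": int(self.support[i]),
                "per_shuffle": per_shuffle,
            })
        return recs


def _true_a_array(table: pd.DataFrame, labels: pd.DataFrame | None) -> np.ndarray:
    if "true_A" in table.columns:
        return table["true_A"].to_numpy()
    if labels is None:
        raise InvalidArgumentError("need a true_A column or a labels table")
    lab = labels.set_index("sample_id")["A"]
    return lab.loc[table["sample_id"].to_numpy()].to_numpy()


def mine_patterns(
    tables: Sequence[pd.DataFrame],
    labels: pd.DataFrame | None = None,
    min_support_shuffles: int = 1,
    model_ids: Sequence[str] = MODEL_IDS,
) -> MiningResult:
    """Exhaustively screen all 3^k − 1 patterns for complete specificity.

    ``tables`` are the per-shuffle *test-subset* prediction tables. A
    pattern qualifies iff every shuffle where it matches at least one
    sample contains matches of only one true fruit-A class, that class is
    identical across all matching shuffles, and it matches in at least
    ``min_support_shuffles`` shuffles. Shuffles with zero matches neither
    qualify nor disqualify.
    """
    model_ids = tuple(model_ids)
    if len(set(model_ids)) != len(model_ids):
        raise InvalidArgumentError(f"duplicate model ids in {model_ids}")
    if not tables:
        raise InvalidArgumentError("need at least one shuffle table")
    n_shuffles = len(tables)
    if not 1 <= min_support_shuffles <= n_shuffles:
        raise InvalidArgumentError(
            f"min_support_shuffles={min_support_shuffles} outside 1..{n_shuffles}"
        )
    for t in tables:
        if len(t) == 0:
            raise InvalidArgumentError("empty shuffle table")

    masks, abits = _pattern_arrays(model_ids)
    n_pat = len(masks)
    NL = np.zeros((n_pat, n_shuffles), dtype=np.int32)
    NH = np.zeros((n_pat, n_shuffles), dtype=np.int32)
    all_bits, all_true = [], []
    for s, table in enumerate(tables):
        rb = encode_predictions(table, model_ids)
        ta = _true_a_array(table, labels)
        all_bits.append(rb)
        all_true.append(ta)
        m = (rb[None, :] & masks[:, None]) == abits[:, None]
        NL[:, s] = m @ (ta == "low").astype(np.int32)
        NH[:, s] = m @ (ta == "high").astype(np.int32)

    matched_any = (NL + NH) > 0
    support = matched_any.sum(axis=1)
    pure_low = (NH == 0).all(axis=1) & (NL > 0).any(axis=1)
    pure_high = (NL == 0).all(axis=1) & (NH > 0).any(axis=1)
    keep = (pure_low | pure_high) & (support >= min_support_shuffles)

    implied = np.where(pure_low[keep], "low", "high").astype(object)
    kept_masks, kept_abits = masks[keep], abits[keep]
    patterns = [
        _pattern_from_bits(int(m), int(a), model_ids, implied=str(d))
        for m, a, d in zip(kept_masks, kept_abits, implied)
    ]
    totals_low = np.array([(t == "low").sum() for t in all_true], dtype=np.int64)
    totals_high = np.array([(t == "high").sum() for t in all_true], dtype=np.int64)
    return MiningResult(
        patterns=patterns,
        support=support[keep],
        model_ids=model_ids,
        masks=kept_masks,
        abits=kept_abits,
        implied=implied,
        n_matched_low=NL[keep],
        n_matched_high=NH[keep],
        totals_low=totals_low,
        totals_high=totals_high,
        row_bits=all_bits,
        true_a=all_true,
    )


def sensitivity_curve(mined: MiningResult, mode: str = "union") -> pd.DataFrame:
    """Sensitivity versus minimum shuffle support m = n_shuffles … 1.

    For each support level m and direction, counts the qualifying patterns
    and summarises their sensitivity (mean ± sample SD). ``mode="union"``
    (default) scores, per shuffle, the percentage of that shuffle's
    true-class test samples matched by the union of qualifying patterns —
    the coverage actually available to a boosted classifier — and averages
    across shuffles. ``mode="per_pattern"`` instead averages each
    qualifying pattern's own mean sensitivity over its matched shuffles.
    Levels with no qualifying pattern report NaN sensitivity.
    """
    if mode not in ("union", "per_pattern"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    rows = []
    S = mined.n_shuffles
    mm_all = [mined.match_matrix(s) for s in range(S)]
    for m in range(S, 0, -1):
        row = {"min_support": m}
        for direction, totals, counts in (
            ("low", mined.totals_low, mined.n_matched_low),
            ("high", mined.totals_high, mined.n_matched_high),
        ):
            q = (mined.implied == direction) & (mined.support >= m)
            row[f"n_patterns_{direction}"] = int(q.sum())
            if not q.any():
                row[f"mean_sensitivity_{direction}"] = np.nan
                row[f"sd_{direction}"] = np.nan
                continue
            if mode == "union":
                per_shuffle = np.empty(S)
                for s in range(S):
                    covered = mm_all[s][q].any(axis=0) & (mined.true_a[s] == direction)
                    per_shuffle[s] = 100.0 * covered.sum() / totals[s]
                vals = per_shuffle
            else:
                sens = 100.0 * counts[q] / totals[None, :]
                matched = (mined.n_matched_low[q] + mined.n_matched_high[q]) > 0
                with np.errstate(invalid="ignore"):
                    vals = np.nansum(np.where(matched, sens, np.nan), axis=1) / matched.sum(axis=1)
            row[f"mean_sensitivity_{direction}"] = float(np.mean(vals))
            row[f"sd_{direction}"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def boost_predictions(row: Mapping, mined: Iterable[Pattern]) -> str:
    """Boosted fruit-A call for one sample from the mined patterns.

    Returns ``"low"``/``"high"`` when at least one mined pattern matches
    and all matching patterns agree, ``"conflict"`` when matching patterns
    disagree, and ``"abstain"`` when none match.
    """
    seen = set()
    for pat in mined:
        if pat.implied_A_class is None:
            raise InvalidArgumentError(f"pattern {pat.name()} has no implied class; mine first")
        if pat.matches(row):
            seen.add(pat.implied_A_class)
    if not seen:
        return "abstain"
    if len(seen) > 1:
        return "conflict"
    return seen.pop()


def boost_many(
    table: pd.DataFrame,
    mined: Sequence[Pattern],
    model_ids: Sequence[str] = MODEL_IDS,
) -> np.ndarray:
    """Vectorised :func:`boost_predictions` over a prediction table.

    Returns one outcome per row (``low``/``high``/``abstain``/``conflict``).
    """
    out = np.full(len(table), "abstain", dtype=object)
    if not mined:
        return out
    bit = {m: b for b, m in enumerate(model_ids)}
    masks = np.zeros(len(mined), dtype=np.int64)
    abits = np.zeros(len(mined), dtype=np.int64)
    implied = np.empty(len(mined), dtype=object)
    for i, pat in enumerate(mined):
        if pat.implied_A_class is None:
            raise InvalidArgumentError(f"pattern {pat.name()} has no implied class; mine first")
        implied[i] = pat.implied_A_class
        for m, c in zip(pat.members, pat.assigned):
            masks[i] |= 1 << bit[m]
            if c == "high":
                abits[i] |= 1 << bit[m]
    rb = encode_predictions(table, model_ids)
    match_m = (rb[None, :] & masks[:, None]) == abits[:, None]
    low_any = match_m[implied == "low"].any(axis=0) if (implied == "low").any() else np.zeros(len(rb), bool)
    high_any = match_m[implied == "high"].any(axis=0) if (implied == "high").any() else np.zeros(len(rb), bool)
    out[low_any & ~high_any] = "low"
    out[high_any & ~low_any] = "high"
    out[low_any & high_any] = "conflict"
    return out


@dataclass(frozen=True)
class PickDecision:
    """Final orchard decision with provenance flags."""

    decision: str          # "Pick" or "Do not Pick"
    resolved_class: str    # "low" or "high"
    used_fallback: bool
    conflict: bool


def decide_pick(boosted: str, fallback: str) -> PickDecision:
    """Pick iff the resolved fruit-A class is *high*.

    High azadirachtin is the commercially desired class. ``abstain`` and
    ``conflict`` outcomes fall back to the raw fruit-A model call so a
    decision is always produced; a conflict is flagged for the report.
    """
    if boosted not in BOOST_OUTCOMES:
        raise InvalidArgumentError(f"unknown boosted outcome {boosted!r}")
    if fallback not in ("low", "high"):
        raise InvalidArgumentError(f"fallback must be low/high, got {fallback!r}")
    if boosted in ("low", "high"):
        resolved, used_fallback, conflict = boosted, False, False
    else:
        resolved, used_fallback, conflict = fallback, True, boosted == "conflict"
    return PickDecision(
        decision="Pick" if resolved == "high" else "Do not Pick",
        resolved_class=resolved,
        used_fallback=used_fallback,
        conflict=conflict,
    )
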