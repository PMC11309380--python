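"""Synthetic neem-orchard data: metabolite concentrations and surrogate predictors.

The real study measured five secondary metabolites — azadirachtin (A),
deacetyl-salannin (D), nimbolide (E), nimbin (N) and salannin (S) — by HPLC
in fruit pooled per tree, and trained ten image models (one per metabolite,
for fruit and for leaf photographs) that each emit a binary *low*/*high*
class call. Neither the images nor the HPLC tables are public, so this
module generates tables with the same statistical shape:

* concentrations drawn from scaled Beta marginals on the published
  per-metabolite ranges, with means matched to the published means, coupled
  through a Gaussian copula so the five analytes are positively correlated;
* ten surrogate predictors with configurable per-class sensitivity,
  conditionally independent given the true class;
* optional *planted rules* — deterministic prediction patterns implying a
  fruit-azadirachtin class — that give the pattern-mining stage a known
  ground truth to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidArgumentError

#: The five metabolites, in canonical order.
METABOLITES: tuple[str, ...] = ("A", "D", "E", "N", "S")

#: The ten image models: one per metabolite for fruit (_f) and leaf (_l) images.
MODEL_IDS: tuple[str, ...] = (
    "A_f", "D_f", "E_f", "N_f", "S_f",
    "A_l", "D_l", "E_l", "N_l", "S_l",
)

CLASSES = ("low", "high")


@dataclass(frozen=True)
class MetaboliteSpec:
    """Marginal concentration distribution of one metabolite.

    Units follow the source assay (relative concentration units). The
    defaults below are the observed range and mean of each analyte across
    the n = 1045 trees of the original survey.
    """

    name: str
    min_conc: float
    max_conc: float
    mean_conc: float

    def __post_init__(self) -> None:
        if self.name not in METABOLITES:
            raise ConfigError(f"unknown metabolite {self.name!r}; expected one of {METABOLITES}")
        if not (self.min_conc < self.mean_conc < self.max_conc):
            raise ConfigError(
                f"{self.name}: need min < mean < max, got "
                f"{self.min_conc} / {self.mean_conc} / {self.max_conc}"
            )

    def beta_shapes(self, concentration: float = 5.0) -> tuple[float, float]:
        """Shape parameters (a, b) of the Beta marginal on [min, max].

        The mean pins a/(a+b); the total concentration a+b is free and
        controls spread (default 5, a broad unimodal shape).
        """
        mu = (self.mean_conc - self.min_conc) / (self.max_conc - self.min_conc)
        return mu * concentration, (1.0 - mu) * concentration


def default_metabolite_specs() -> list[MetaboliteSpec]:
    """Published concentration ranges and means for A, D, E, N, S."""
    return [
        MetaboliteSpec("A", 0.181, 1.003, 0.563),
        MetaboliteSpec("D", 0.007, 0.691, 0.112),
        MetaboliteSpec("E", 0.004, 0.252, 0.045),
        MetaboliteSpec("N", 0.009, 0.501, 0.163),
        MetaboliteSpec("S", 0.056, 1.420, 0.511),
    ]


@dataclass(frozen=True)
class PredictorSpec:
    """Operating point of one surrogate image model.

    ``sens_low``/``sens_high`` are the per-class sensitivities: the long-run
    probability that a sample whose true class is low (resp. high) for the
    model's metabolite is called low (resp. high).
    """

    model_id: str
    sens_low: float
    sens_high: float

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ConfigError(f"unknown model_id {self.model_id!r}; expected one of {MODEL_IDS}")
        for v in (self.sens_low, self.sens_high):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{self.model_id}: sensitivity {v} outside [0, 1]")

    @property
    def metabolite(self) -> str:
        return self.model_id[0]


def default_predictor_specs() -> list[PredictorSpec]:
    """Per-class sensitivities near the reported test-set operating points.

    Fruit models are strong (the fruit-A model sits near its reported
    83.5 / 82.4 per-class sensitivities; D and S fruit models are the best
    performers), leaf models markedly weaker — mirroring the reported
    fruit >> leaf performance gap.
    """
    return [
        PredictorSpec("A_f", 0.84, 0.82),
        PredictorSpec("D_f", 0.93, 0.91),
        PredictorSpec("E_f", 0.87, 0.89),
        PredictorSpec("N_f", 0.88, 0.85),
        PredictorSpec("S_f", 0.96, 0.98),
        PredictorSpec("A_l", 0.73, 0.70),
        PredictorSpec("D_l", 0.68, 0.72),
        PredictorSpec("E_l", 0.60, 0.63),
        PredictorSpec("N_l", 0.71, 0.75),
        PredictorSpec("S_l", 0.70, 0.67),
    ]


@dataclass(frozen=True)
class PlantedRule:
    """A deterministic prediction pattern implying a fruit-A class.

    Ground-truth plumbing for recovery tests: samples whose true fruit-A
    class equals ``implied_class`` receive the antecedent predictions
    (members set to their assigned classes) with probability
    ``coverage * penetrance``; every other sample that would match the
    antecedent by chance has it broken (one member flipped) with
    probability ``penetrance``. At penetrance 1.0 the antecedent therefore
    matches exactly the planted set: only implied-class samples, covering
    a ``coverage`` fraction of them.
    """

    members: tuple[str, ...]
    assigned: tuple[str, ...]
    implied_class: str
    penetrance: float = 1.0
    coverage: float = 1.0

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigError("planted rule needs at least one member model")
        for m in self.members:
            if m not in MODEL_IDS:
                raise ConfigError(f"unknown model_id {m!r} in planted rule")
        if len(set(self.members)) != len(self.members):
            raise ConfigError("duplicate members in planted rule")
        if len(self.assigned) != len(self.members):
            raise ConfigError("assigned classes must align with members")
        for c in self.assigned:
            if c not in CLASSES:
                raise ConfigError(f"invalid class {c!r}")
        if self.implied_class not in CLASSES:
            raise ConfigError(f"invalid implied class {self.implied_class!r}")
        if not 0.0 < self.penetrance <= 1.0:
            raise ConfigError(f"penetrance {self.penetrance} outside (0, 1]")
        if not 0.0 < self.coverage <= 1.0:
            raise ConfigError(f"coverage {self.coverage} outside (0, 1]")


def _validate_rules(rules: list[PlantedRule]) -> None:
    # Two rules implying the same class must not assign conflicting values
    # to a shared member; rules implying opposite classes act on disjoint
    # samples and cannot contradict.
    for i, r in enumerate(rules):
        for s in rules[i + 1:]:
            if r.implied_class != s.implied_class:
                continue
            ra = dict(zip(r.members, r.assigned))
            sa = dict(zip(s.members, s.assigned))
            for m in set(ra) & set(sa):
                if ra[m] != sa[m]:
                    raise ConfigError(
                        f"planted rules contradict on {m}: {ra[m]} vs {sa[m]} "
                        f"for implied class {r.implied_class}"
                    )


def _check_correlation(corr: np.ndarray, k: int) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (k, k):
        raise ConfigError(f"correlation matrix must be {k}x{k}, got {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ConfigError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ConfigError("correlation matrix must have unit diagonal")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ConfigError(f"correlation matrix is not positive semi-definite (min eigenvalue {eigvals.min():.3g})")
    return corr


def default_correlation(rho: float = 0.3) -> np.ndarray:
    """Exchangeable positive correlation among the five metabolites.

    No inter-metabolite correlation estimates were published; a modest
    uniform rank correlation of 0.3 stands in for co-regulated limonoid
    biosynthesis.
    """
    k = len(METABOLITES)
    return np.full((k, k), rho) + (1.0 - rho) * np.eye(k)


def simulate_concentrations(
    n: int,
    specs: list[MetaboliteSpec] | None = None,
    correlation: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw ``n`` per-tree concentration records.

    Marginals are Beta distributions rescaled to each metabolite's
    [min, max] with the mean matched exactly; dependence is a Gaussian
    copula whose latent correlation is adjusted (2·sin(π·ρ/6)) so the
    empirical Spearman correlation converges to ``correlation``.

    Returns a DataFrame with columns ``sample_id, A, D, E, N, S``.
    """
    if n < 1:
        raise InvalidArgumentError(f"need n >= 1 samples, got {n}")
    specs = specs if specs is not None else default_metabolite_specs()
    if [s.name for s in specs] != list(METABOLITES):
        raise ConfigError(f"specs must cover {METABOLITES} in order")
    k = len(specs)
    corr = _check_correlation(
        correlation if correlation is not None else np.eye(k), k
    )
    rng = np.random.default_rng(seed)

    # Spearman -> Gaussian latent correlation, then repair PSD if the
    # element-wise map pushed an eigenvalue slightly negative.
    latent = 2.0 * np.sin(np.pi * corr / 6.0)
    np.fill_diagonal(latent, 1.0)
    eigvals, eigvecs = np.linalg.eigh(latent)
    if eigvals.min() < 0:
        eigvals = np.clip(eigvals, 1e-12, None)
        latent = eigvecs @ np.diag(eigvals) @ eigvecs.T
        d = np.sqrt(np.diag(latent))
        latent = latent / np.outer(d, d)

    z = rng.multivariate_normal(np.zeros(k), latent, size=n, method="cholesky")
    from scipy import stats

    u = stats.norm.cdf(z)
    data = {"sample_id": [f"T{i:05d}" for i in range(n)]}
    for j, spec in enumerate(specs):
        a, b = spec.beta_shapes()
        x = stats.beta.ppf(u[:, j], a, b)
        data[spec.name] = spec.min_conc + x * (spec.max_conc - spec.min_conc)
    return pd.DataFrame(data)


def simulate_predictions(
    records: pd.DataFrame,
    labels: pd.DataFrame,
    predictors: list[PredictorSpec] | None = None,
    rules: list[PlantedRule] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Emit a sample × model prediction table.

    Each surrogate model calls its metabolite's true class correctly with
    the per-class sensitivity in its :class:`PredictorSpec` and flips it
    otherwise, independently across models given the truth — the least
    favourable regime for pattern mining, since any real inter-model
    correlation would only make deterministic patterns easier to find.
    Planted rules then overwrite member predictions (see
    :class:`PlantedRule`).

    Returns a DataFrame with ``sample_id``, ``true_<metabolite>`` columns
    and ``pred_<model_id>`` columns, classes as ``"low"``/``"high"``.
    """
    predictors = predictors if predictors is not None else default_predictor_specs()
    rules = rules or []
    _validate_rules(rules)
    ids = {p.model_id for p in predictors}
    if ids != set(MODEL_IDS):
        missing = set(MODEL_IDS) - ids
        extra = ids - set(MODEL_IDS)
        raise ConfigError(f"predictor specs must cover the ten models exactly (missing {missing}, extra {extra})")

    lab = labels.set_index("sample_id")
    missing_samples = set(records["sample_id"]) - set(lab.index)
    if missing_samples:
        raise InvalidArgumentError(f"labels missing for {len(missing_samples)} samples")
    lab = lab.loc[records["sample_id"].to_numpy()]

    rng = np.random.default_rng(seed)
    n = len(records)
    out = pd.DataFrame({"sample_id": records["sample_id"].to_numpy()})
    for m in METABOLITES:
        out[f"true_{m}"] = lab[m].to_numpy()

    pred = {}
    for p in sorted(predictors, key=lambda p: MODEL_IDS.index(p.model_id)):
        truth = lab[p.metabolite].to_numpy()
        is_high = truth == "high"
        correct = np.where(is_high, rng.random(n) < p.sens_high, rng.random(n) < p.sens_low)
        calls = np.where(correct, truth, np.where(is_high, "low", "high"))
        pred[p.model_id] = calls

    true_a = lab["A"].to_numpy()
    for rule in rules:
        implied = true_a == rule.implied_class
        # plant the antecedent on covered implied-class samples
        plant = implied & (rng.random(n) < rule.coverage) & (rng.random(n) < rule.penetrance)
        for m, c in zip(rule.members, rule.assigned):
            pred[m] = np.where(plant, c, pred[m])
        # break chance matches on every non-planted sample, so the antecedent
        # identifies exactly the planted set (at penetrance 1.0)
        match = ~plant
        for m, c in zip(rule.members, rule.assigned):
            match &= pred[m] == c
        to_break = match & (rng.random(n) < rule.penetrance)
        if to_break.any():
            pick = rng.integers(0, len(rule.members), size=n)
            for j, (m, c) in enumerate(zip(rule.members, rule.assigned)):
                flip = to_break & (pick == j)
                other = "low" if c == "high" else "high"
                pred[m] = np.where(flip, other, pred[m])

    for m in MODEL_IDS:
        out[f"pred_{m}"] = pred[m]
    return out
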