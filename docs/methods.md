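# Methods

## Scope and model

The package reconstructs, as a testable pipeline, a multi-analyte
framework for predicting a neem tree's fruit-azadirachtin concentration
class from ten binary image-model outputs. The deep networks themselves
are out of scope: their behaviour is emulated by surrogate predictors
with configurable per-class sensitivity, so every downstream stage —
labeling, splitting, mining, boosting, decision — is exercised under
controlled, reproducible conditions.

## Synthetic data generator

**Concentrations.** Each metabolite's marginal is a Beta distribution
rescaled to its published range, with the Beta mean pinned to the
published mean: for range [lo, hi] and mean μ the standardised mean is
(μ − lo)/(hi − lo), and the total concentration a + b is a free shape
parameter fixed at 5 (a broad unimodal density; the source distributions
are right-skewed box plots, which a Beta with this spread reproduces
qualitatively). Bounded support means no truncation or clipping is ever
applied. Defaults (concentration units): A 0.181–1.003 mean 0.563,
D 0.007–0.691 mean 0.112, E 0.004–0.252 mean 0.045, N 0.009–0.501 mean
0.163, S 0.056–1.42 mean 0.511.

**Dependence.** The five marginals are coupled by a Gaussian copula. The
requested matrix is interpreted as a Spearman rank correlation and mapped
to the latent Gaussian correlation via ρ_gauss = 2·sin(π·ρ_s/6), so the
empirical rank correlation converges to the requested values; if the
element-wise map leaves the matrix slightly indefinite it is projected
back to the nearest correlation matrix by eigenvalue clipping. No
inter-metabolite correlation estimates were published; the experiment
default is an exchangeable ρ_s = 0.3, a modest positive coupling
consistent with co-regulated limonoid biosynthesis. It is a free
simulation parameter.

**Surrogate predictors.** Given the true class of its metabolite, each
model calls it correctly with probability sens_low or sens_high and flips
it otherwise, independently across models. Conditional independence is
the least favourable regime for pattern mining — any real inter-model
correlation could only make deterministic structure easier to find — and
is stated explicitly because the real inter-model dependence is unknown.
Default operating points sit near the reported test-set metrics: the
fruit-A model at (0.84, 0.82), the other fruit models between 0.85 and
0.98, the leaf models markedly weaker (0.60–0.75), mirroring the reported
fruit ≫ leaf gap.

**Planted rules.** A planted rule forces a chosen prediction tuple to
identify a known subset of one fruit-A class: implied-class samples
receive the antecedent with probability coverage × penetrance, and every
other sample that would match it by chance has one member flipped with
probability penetrance. At penetrance 1.0 the antecedent therefore
matches exactly the planted set, which makes both recovery (the pattern
must be mined at full support) and calibration (its measured sensitivity
must equal the planted coverage) sharply testable. The suppression step
slightly perturbs the member models' marginal sensitivities; rules are
applied in order, and rules implying the same class may not assign
conflicting values to a shared member. At penetrance < 1, chance matches
on the wrong class survive, so recovery probability falls as penetrance
falls.

**What the generator does not emulate.** Image content, detector
confidence values, inter-model error correlation, spatial/geographic
structure among trees, assay noise in HPLC, and the small fruit/leaf
image-count discrepancies present in the original dataset. Passing tests
therefore certify the *pipeline logic* (labeling arithmetic, split
bookkeeping, the complete-specificity screen, boosting semantics, metric
algebra), not field performance of any image model.

## Labeling and splits

Classes are formed per metabolite by thresholding at the empirical mean;
a value exactly at the threshold is labelled low (a deterministic tie
rule; ties have measure zero for continuous assays). Missing
concentrations exclude the sample with a logged warning. Splits are
simple random 80:10:10 permutations, independent per shuffle — not
disjoint folds, matching the protocol being reconstructed — with subset
sizes ⌊n·r⌋ for validation and test and the remainder to train (1045 →
837/104/104). Stratified splitting is available behind a flag but off by
default, since the reconstructed protocol shows unequal class counts
across splits.

## Metrics

F1 is the harmonic mean 2PR/(P + R), defined as 0 at P = R = 0. The
combined-class ("a") precision/recall/F1 are macro averages of the two
per-class values. Sensitivity and specificity are reported as percentages
with empty-class cases returned as undefined rather than zero. The
cross-validation error is the mean of per-shuffle errors with the sample
(n − 1) SD; the per-class error is defined as 1 − sensitivity (as a
proportion), one of several definitions consistent with the reconstructed
report, whose exact convention is ambiguous. Detection mAP is not
implemented: it belongs to the out-of-scope detector training.

## Pattern mining

Patterns are encoded as bitmasks over the ten models (member mask +
assignment bits, low = 0), enumerated exhaustively in a fixed order
(subset masks ascending, assignments in binary order) for diffable
output: 3^k − 1 patterns, 59 048 for k = 10. Matching a whole shuffle
against all patterns is two vectorised integer operations, so the full
enumeration over ten shuffles of ~104 test samples runs in seconds and no
heuristic search is needed.

The complete-specificity screen reduces to: a pattern qualifies for class
c iff it matches no sample of the other class in any shuffle and at least
one sample of class c somewhere. Shuffles with zero matches neither
qualify nor disqualify; support counts matching shuffles only, and
direction consistency across shuffles is required. Per-shuffle pattern
sensitivity is 100 × (matched samples of the implied class)/(test samples
of that class).

The sensitivity-versus-support curve is computed under two semantics:
**union coverage** (default) — per shuffle, the percentage of true-class
test samples matched by the union of qualifying patterns, averaged across
shuffles — and per-pattern averaging. Union coverage is the default
because it is the sensitivity actually available to a boosted classifier,
and because reported boosted sensitivities exceed any plausible single
pattern's. Boosting returns the unanimous implied class of matching
patterns, with abstain/conflict outcomes; on selection shuffles conflicts
are impossible (a sample cannot match both a pure-low and a pure-high
pattern there). The Pick decision maps the resolved class high → Pick,
resolving abstain and conflict through the raw fruit-A call so the
decision stage always answers; conflicts are flagged.

Selection and evaluation deliberately share the same test shuffles in the
default protocol, as in the procedure being reconstructed; the 100 %
boosted specificity is therefore a by-construction property of the
selection set, not an out-of-sample estimate. An honest-evaluation mode
(`holdout=True`) mines on the first S − 1 shuffles and scores only the
last.

## Detector pre/post-processing

Letterboxing scales by s = target/max(h, w), pastes centred on a
114-grey canvas, then transposes to channel-first, converts BGR→RGB and
rescales to [0, 1]; the metadata (s, pad offsets) inverts the transform
to better than half a pixel. Padding is centred because the referenced
letterbox utility centres; the NMS IoU threshold defaults to 0.45 (the
detector family's default — only the 0.25 confidence cutoff is fixed by
the pipeline) and is exposed as a parameter. NMS is greedy by descending
confidence within class, with ties and top-1 ties broken by input order
for determinism.

## Numerical and reproducibility choices

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawning (concentrations, splits, one stream
per shuffle's predictions), so identical configurations produce
byte-identical outputs. Aggregates use the sample SD (ddof = 1) over
shuffles. Percentages are serialized to 2 decimals. Problem sizes in the
test suite follow the study conditions where the contract is about the
study (n = 1045, ten shuffles, full enumeration); unit tests use smaller
n only where the property under test is size-free.

## Known limitations

- The surrogate predictors are conditionally independent given the true
  class; real image models share failure modes, which would change the
  spurious-pattern count (though not the complete-specificity guarantee).
- With tens of thousands of spurious complete-specificity patterns at
  survey scale, union coverage saturates near 100 %; distinguishing
  planted from spurious structure out of sample requires the holdout
  mode.
- The copula correlation and the Beta spread parameter are simulation
  choices, not estimates.
- Pattern mining assumes binary classes throughout; multi-level
  concentration classes would need a different screen.
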