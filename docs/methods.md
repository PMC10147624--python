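# Methods

`histotriage` evaluates a slide-level mutation-risk score — typically the
output of a deep-learning model on histopathology — as a *first-line gate*
before gold-standard DNA sequencing. This note documents the statistical
model behind each stage, the defaults and why, and the limits of what the
synthetic experiments demonstrate.

## The two-step pipeline and its metrics

Each slide receives a risk score for a given gene; slides scoring at or
above a threshold are sent to sequencing, which is modelled as a perfect
test (sensitivity and specificity 1). With `P` truly mutated slides out of
`n`, the quantities of interest at an operating point are

- `Se(X) = TP / P` — sensitivity of the whole gate-then-sequence pipeline,
- `P(DL)`, `N(DL)` — fractions called positive / negative by the gate
  (`P(DL) + N(DL) = 1`),
- `PPV` — fraction of gate-selected slides truly mutated,
- `RR = PPV / prevalence` and the odds ratio of the selected-by-mutated
  2×2 table.

## Triage strategies

All three strategies are constrained optimizations over the threshold, and
all depend on scores only through their ranks (any strictly monotone
rescaling leaves them unchanged; this is asserted by tests).

**Save-all** maximizes `N(DL)` subject to `Se(X) ≥ T` (default `T = 0.95`).
The finite-sample constraint is `TP ≥ ⌈T·P⌉`, read from the "≥" in the
constraint. Candidate thresholds are the observed score values plus `+∞`.
When only "test everyone" satisfies the constraint the operating point is
returned with `N(DL) = 0` and an explicit `feasible=False` flag.

**Fixed-capacity** maximizes `Se(X)` subject to `P(DL) ≤ T`
(`T ∈ {0.30, 0.50, 0.70}` by default): the `⌊T·n⌋` highest-scoring slides
are sequenced. `⌊·⌋` keeps the budget constraint an inequality; boundary
ties are broken by slide identifier — clinically arbitrary, but it makes
results reproducible and never exceeds the budget. An uninformative gate
attains `Se(X) = T` in expectation, the natural baseline.

**Prioritize** fast-tracks the top `max(1, ⌊T·n⌋)` slides
(`T ∈ {0.05, 0.10}`) and reports PPV, `RR = PPV / prevalence`, and the
odds ratio `(a·d)/(b·c)` of the 2×2 table, with a Haldane–Anscombe +0.5
correction on all cells when any cell is zero (flagged on the result). The
odds ratio is the prevalence-free companion to RR: correlating each against
prevalence across genes separates intrinsic test evidence from prevalence
artefacts (`prevalence_dependence`).

**Cross-validation.** Strategies are evaluated per fold of a site-disjoint
k-fold plan (k = 5 default) and reported as mean ± *standard deviation of
the mean*, i.e. sample SD across folds divided by √(folds used). A raw-SD
toggle exists because the phrase is ambiguous in common usage. Folds whose
test side lacks a label class are skipped with a warning and the divisor
shrinks accordingly.

## Site-aware splitting

Tissue-source sites (field 2 of a TCGA barcode) proxy staining/scanner
batches; splits are site-atomic to avoid leakage. The assignment algorithm
is: shuffle sites by seed, stable-sort by size descending, then greedily
place each site in the fold with the lexicographically best (size fill
ratio, positive-count imbalance, fold index), with a guard that never
leaves a fold empty. The constraint (site disjointness) is hard;
stratification is best-effort — sites cannot be split, so exact
stratification is generally unattainable. On equal sites the greedy
assignment hits target fractions exactly; on unequal sites the deviation is
bounded by the largest single-site share (property-tested over 100 seeds).

## Tile model and aggregation

The default slide scorer is an ensemble of 3 multilayer perceptrons
(hidden layers 64 and 16, ReLU, sigmoid output) trained for 5 epochs with
Adam at learning rate 1e-4, batch size 32, on binary cross-entropy, every
tile inheriting its slide's label. Member probabilities are averaged per
tile; the slide score is the **99th percentile** of its tile scores
(linear interpolation between closest ranks, the convention of the
surrounding numerical stack). The high percentile reflects the assumption
that mutation-associated morphology affects a minority of tiles: a mean
would dilute a 10%-tile signal, a near-max preserves it (asserted
end-to-end on a fixed seed). The trainer is scikit-learn's MLPClassifier;
the classifier is pluggable behind a fit/predict-proba contract and a
logistic-regression base is provided for fast tests. Batch size, weight
initialization and shuffling are fixed by seed so runs are reproducible.

## Predictability screen

Per gene, the model is trained `r = 5` times with independent seeded
initializations on the train side of one fixed 70/30 site-disjoint holdout;
the test-side AUC replicates are tested against 0.5 with a one-sided
one-sample t-test (`t = (mean − 0.5)/(sd/√r)`, df `r − 1`; normality
assumed, no nonparametric fallback), and Benjamini–Hochberg at FDR 0.05 is
applied jointly across all genes of the run. AUC is the Mann–Whitney
probability with ties counted ½, computed by the rank formula and
cross-checked in tests against both brute-force pair enumeration and
scikit-learn. Replicates that are all identical raise an explicit
degenerate-variance error rather than reporting `t = ∞`.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, and only that:

- **Sites**: equal sizes by default; a log-normal dispersion parameter
  produces unequal sites to stress the splitter. Patients default to one
  slide each (multi-slide patients available by config).
- **Labels**: per-gene Bernoulli at configured prevalence. Defaults in
  examples span 0.1–0.7, chosen to bracket the >10% prevalence inclusion
  rule rather than to replicate any particular tumor type.
- **Scores**: a binormal latent `L = μ·y + ε`, `ε ~ N(0,1)`, with
  `μ = √2·Φ⁻¹(AUC)` so the theoretical AUC is exact; latents are squashed
  to [0, 1] by a standard logistic map (rank-equivalent for every
  consumer).
- **Tiles**: a configurable fraction of each slide's tiles (default 0.1)
  shares the slide latent plus N(0, 0.25²) jitter; the rest sit at a low
  background level. Because signal tiles dominate the upper tail, the
  99th-percentile aggregate recovers the slide latent and hence the
  calibrated AUC. A per-slide latent is necessary here: a pure tile-level
  mixture would concentrate the percentile's variance away as
  tiles-per-slide grows and overshoot the target AUC. Optional tile
  feature vectors (signal tiles of mutated slides shifted by 3 along the
  first axis) exercise the classifier path.

What the generator does **not** emulate: real embedding geometry,
site-level batch effects on the scores themselves, correlated genes,
label noise, or heterogeneous per-slide tile counts. Passing tests
demonstrate the correctness and calibration of the *evaluation machinery*,
not the clinical performance of any real scorer.

## Inequality analysis

For capacities 0.30/0.50/0.70/1.00, the mean fixed-capacity sensitivities
of the top 5 genes (ranked at capacity 0.50 by default, equal weights,
ties by gene name) are compared with the random baseline (= capacity). Gaps
are distances in percentage points to the full-capacity population;
`relative_gap_reduction = (gap_random − gap_DL)/gap_random`. At capacity
1.0 both allocations reach sensitivity 1 and the row is analytic.

## Numerical choices and degenerate inputs

- Ceil/floor of products like `0.95·P` are guarded with a 1e-9 epsilon
  against binary-representation noise.
- Capacity selecting zero slides, single-class label vectors,
  zero-variance replicates, zero prevalence, and sub-k site counts all
  raise typed errors rather than returning silently degenerate values.
- One user seed is fanned out to stages via CRC-32 of
  `"seed:stage:gene:rep"`, so per-gene results are independent of gene
  ordering and stages can be rerun in isolation.

## Problem sizes in the shipped experiments

The test suite and the reproduction script use cohorts of 500–2000 slides,
500 Monte-Carlo replicates for stochastic checks, 200 genes for the
complete-null screen calibration, and 1000 random micro-cohorts (≤30
slides) for brute-force oracle equivalence — sizes at which Monte-Carlo
standard errors are small relative to the tolerances asserted.
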