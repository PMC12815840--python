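# Methods

## Problem and model

`coasel` addresses wrapper feature selection for two-class (and, for the
metrics, multiclass) feature matrices of the kind produced by EEG
motor-imagery pipelines: `n` trials by `d` extracted features, with many
columns irrelevant to the class. Two independent selectors are provided
— a stochastic population search and an exact constrained 0/1 program —
plus the signal front-end that produces such matrices and the harness to
evaluate a selected subset. The two selectors are not composed; they are
alternative formulations of the same selection problem.

### Coati search

Candidate subsets are binary masks. The objective is
`f(X) = 1 − Acc(X)` with `Acc` the leave-one-out cross-validated
accuracy of a 1-nearest-neighbor Euclidean classifier on the masked
matrix. Design choices that the formulation leaves open were resolved as
follows:

- **Empty mask.** Fitness 1.0 (worst) by convention, without invoking
  the classifier. This keeps the search space closed under bit-flips and
  movement; no repair operator is used, so the search is not biased
  toward any cardinality.
- **1-NN ties.** Broken toward the lowest training-row index
  (`argmin` order), making fitness deterministic and order-stable.
  LOOCV is consequently equivariant under sample permutation.
- **Leader exemption.** The per-iteration update loop skips the current
  leader: it is neither moved nor opposed, and is replaced only when
  another coati attains strictly lower fitness. This is what makes the
  best-fitness trace non-increasing (elitism). An alternative reading
  applies opposition to every coati including the leader; since
  opposition only ever accepts strict improvements this would also
  preserve elitism, but the exempt-leader form is the one implemented.
- **Switching rule.** Per bit, fresh draws `r1, r2, u ~ U(0,1)`; the
  leader's bit is adopted iff `u < r1·(1 − r2·x)`. Drawing per bit is
  the only reading under which the per-bit adoption test is meaningful.
  A set bit (x = 1) has a reduced switching probability, i.e. the
  representation is "sticky" on selected features. No further adaptive
  schedule or movement coefficient exists — the method is parameter-free
  beyond `N`, `T` and the initialization probability `p`.
- **Draw order.** One seeded `numpy` Generator: initialization bits
  row-major (coati outer, bit inner); then per iteration, per non-leader
  coati in index order, `r1, r2, u` per bit. Fixing this order makes runs
  bit-identical for a given seed.
- **Caching.** Fitness values are memoized by exact bit string within a
  run; the dominant cost of the search is repeated LOOCV, which for the
  bundled 1-NN is evaluated vectorized via a full pairwise-distance
  matrix with the diagonal masked.

Defaults: `N = 20`, `T = 50`, `p = 0.5`. Termination is `T` iterations
or an early stop once the best fitness improves by less than
`early_stop_eps = 1e-6` over the last `early_stop_window = 10`
iterations; the stall window is a pragmatic reading of "minimal
improvement over recent generations" and both knobs are exposed on the
API and CLI. The classifier behind the fitness is pluggable (any object
with deterministic `fit`/`predict`); only 1-NN is bundled and tested.

### Constrained 0/1 selection

Relevance scores `s_j ∈ [0,1]`, costs `c_j`, latencies `r_j` and group
flags `g_j` define `max Σ s_j z_j` subject to `Σ c_j z_j ≤ B`,
`Σ r_j z_j ≤ R`, `Σ z_j ≤ k`, `Σ g_j z_j ≥ Gmin`. `solve_lp_selection`
solves this exactly with HiGHS branch and bound over the LP relaxation;
`enumerate_optimum` is the brute-force oracle (guarded at `d ≤ 20`,
ties to the lexicographically smallest bit string) used to validate the
solver on random and boundary instances. Because nothing in the
formulation ties the scores to data, the bundled default scorer is a
per-feature Fisher ratio (between-class over within-class variance,
rescaled to max 1, with a tiny ridge so perfectly separating features
stay finite and constant features score 0); scores may equally be
supplied from file, and costs/latencies default to 1 each.

## Signal front-end

Epoched trials (trials × channels × time, with sampling rate and
labels) pass through:

- **Normalization** — z-score (population SD, per trial per channel;
  zero-variance channels map to zeros) is the default; min–max onto
  [0,1] is the documented alternative (`--normalize {zscore,minmax,none}`).
  Both appear in the motor-imagery literature; per-trial statistics were
  chosen because the per-channel moments are defined over a single
  epoch matrix.
- **Band-pass** — zero-phase Butterworth (order 4 default), default band
  8–30 Hz covering the mu and beta rhythms that carry motor-imagery
  effects. Artifact handling beyond filtering is out of scope.
- **Features** — time-domain moments (mean, population variance,
  skewness; skewness 0 for constant channels); Welch band power
  (1 s segments, 50% overlap, trapezoid integration) over canonical
  bands delta 1–4, theta 4–8, alpha 8–13, beta 13–30 Hz; and CSP.
- **CSP** — class-average, trace-normalized covariances with a diagonal
  ridge of 1e-8 of the trace; generalized eigenproblem
  `C1 w = λ (C1 + C2) w`; `m = 3` pairs retained from the two ends of
  the spectrum. The whitening identity `λ_k^{(1)} + λ_k^{(2)} = 1` holds
  per retained component (to ~1e-8 given the ridge). Transform features
  are log variance shares, floored at 1e-12 before the log.

Wavelet features and EDF/BCI2000 ingestion are extension points, not
implemented.

## Synthetic benchmarks

The generators produce the statistical structure the selectors assume,
with the planted truth returned for recovery tests:

- **Tabular** — `k` informative columns drawn class-conditionally
  N(±effect/2, 1), the rest standard normal independent of the label.
  Defaults n = 200, d = 30, k = 5, effect = 1.5 (a strong but not
  trivial univariate separation: single-feature Bayes error ≈ 23%),
  balanced classes. Noise columns are independent — no correlation
  structure or channel covariance is emulated, so passing recovery tests
  demonstrates search behavior under the independent-noise regime, not
  performance on real EEG.
- **Signals** — background 1/f-ish noise (cumulative-summed white noise,
  re-centered, blended with a white component and scaled to unit SD; the
  exact spectral slope is not asserted), with class-1 trials adding a
  band-centre sinusoid of amplitude `snr` and uniform random phase on
  the designated channels. Defaults: 60 trials, 8 channels, 2 s at
  160 Hz, alpha band 8–12 Hz, snr = 2.

## Evaluation

Metrics come from the confusion table for a stated positive label
(macro one-vs-rest for >2 classes). Zero-denominator precision/recall
are reported as 0 with an explicit `degenerate` flag so pooled
aggregation never produces NaN. `evaluate_mask` pools held-out
predictions over seeded stratified k-fold (default 5) or leave-one-out;
if stratification cannot give every fold every class the fold count is
reduced with a warning. Reports embed the mask's reduction rate
`1 − selected/d`.

## Worked example and recomputed values

The bundled 5×6 fixture is used throughout the tests. Two of its
in-text narrative values are internally inconsistent with its own
printed matrix: recomputing from the matrix gives S1→S3/S4/S5 distances
of 0.8737/0.9116/0.8016 on features f1, f3, f5, and exhaustive LOOCV
scores the masks `[0,1,1,1,0,1]` and `[1,1,0,1,0,1]` at accuracy 1.0
rather than 0.8/0.6. The implementation and tests follow the formulas
and the printed matrix; the recomputed values are asserted by an
independent plain-loop oracle in the test suite.

## Problem sizes

Test and acceptance runs are sized for a single CPU: recovery runs use
n = 200, d = 30 with N = 20, T = 50 over 10 seeds (~2 s total thanks to
the vectorized LOOCV and fitness cache); solver-vs-oracle equivalence
uses 100 random instances at d = 12; property sweeps use n = 60, d = 12
populations. These sizes are the package's own benchmark defaults.

## Known limitations

- Wrapper fitness with 1-NN LOOCV measures subset quality on the
  selection data itself; selected subsets should be re-validated on
  held-out data (the evaluation module supports this but the search does
  not hold data out internally).
- The fitness does not penalize cardinality, so among equally accurate
  subsets the search has no pressure toward the smallest one beyond what
  opposition happens to find.
- CSP assumes exactly two classes and stationary covariances within a
  trial; the synthetic signal generator does not emulate artifacts,
  inter-subject variability, or realistic channel covariance.
- Benchmark-scale claims on public EEG corpora require external
  recordings and trained deep classifiers; nothing at package scale
  stands in for them, and no such numbers are reported here.
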