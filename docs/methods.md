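# Methods

This note documents the models, estimators and numerical choices behind
`tastedyn`, in the spirit of a package's statistical reference manual. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Session model and epochs

All times are milliseconds, floating point, on a session clock with origin
at session start. A trial records the stimulus concentration (one of
{0, 0.5, 1.3, 3.2, 7.9, 20} %w/v; 0 is the water category), the animal's
binary choice, the derived outcome (`correct` iff choice matches the
stimulus category) and reward flag, and its behavioral events: stimulus
delivery, central-spout licks (≥2), lateral-spout licks, and feedback
defined as the **second lateral lick** — the moment reward is delivered or
omitted. Trials with fewer than two lateral licks (early aborts) are
retained and flagged but excluded from every feedback-aligned analysis.

Analysis epochs use 100 ms windows sliding in 10 ms steps. Windows are
half-open `[t0, t0 + w)` so boundary spikes are counted exactly once, and
each bin is timestamped at its **window center**, which keeps
latency-to-peak statistics symmetric (the alternative, edge timestamps, is
an arbitrary 50 ms shift). Defaults: stimulus epoch −400…+800 ms around
delivery; choice epoch −300…+800 ms around the last central lick; outcome
epoch −300…+800 ms around feedback. Bin count `B = floor((t_end − t_start
− w)/s) + 1`.

## Synthetic sessions

The generator is first-class, tested code: it defines the conditions under
which every downstream stage is validated.

**Behavior.** The stimulus is water with probability 0.5, otherwise uniform
over the five sucrose concentrations. The choice is Bernoulli with
`p(sucrose | c) = clip(a·c^b, ε, 1 − ε)`; a clipped power law rather than a
logistic so the psychometric fitter can recover the generative parameters
exactly in the noise-free limit. Defaults `a = 0.59`, `b = 0.16` place the
50% point near 0.35 %w/v and the 20% point near 0.95 — a rat that
categorizes the extremes reliably and confuses near-threshold sucrose with
water; the lapse `ε = 0.05` doubles as the false-alarm rate at c = 0.
Inter-lick intervals are i.i.d. Normal(140, 15) ms truncated at 60 ms
(licking is rhythmic at ~7 Hz); trials have 2–3 central licks with the
stimulus at the first, a movement delay of ~320 ms, and 4–6 lateral licks
with feedback at the second.

**Spiking.** Each neuron is an inhomogeneous Poisson process with rate
`λ(t) = λ0 + Σ_bumps [condition = preferred] · ΔΛ · exp(−(t − t_align −
μ)² / 2σ²)`. Sampling uses superposition — a homogeneous baseline process
plus a Poisson(`ΔΛ·σ·√(2π)/1000`) number of Normal(μ, σ) bump spikes per
matching trial — which is exact for this rate family. No refractoriness:
rank-based auROC statistics are insensitive to it, and Poisson is the
simplest process satisfying every assumption the analyses make. Switching
neurons carry two opposite-preference bumps in the same epoch.

**Templates.** `null`: 50 untuned neurons. `perfect_sequence`: 20 neurons,
baseline 0.5 Hz, 45 Hz bumps of σ = 15 ms at latencies uniformly spaced
over [0, 800] ms — non-overlapping encoding fields. `encoders_mixed`
(200 trials): 15 stimulus-, 20 choice- (4 switching), 30 outcome-tuned and
35 untuned neurons; baselines uniform in 2–8 Hz, bumps 22 Hz with
σ = 50–55 ms, centers tiling [40, 700] ms of each variable's epoch. These
amplitudes give high but unsaturated detection power at ~200 trials.

What the generator does **not** emulate: rate drift and non-stationarity,
correlated (shared) variability across neurons, non-Poisson dispersion,
bursting, behavioral dependence of lick counts on outcome, and
session-to-session learning. Passing recovery tests therefore demonstrate
correctness of the estimators under their own assumptions, not robustness
to every property of real recordings.

## Encoding screen

Per neuron and bin, auROC between the two classes' rate distributions via
pooled mid-ranks: `A = (ΣR_high − n_h(n_h+1)/2)/(n_l·n_h)`, i.e.
`P(X_high > X_low) + ½P(=)`; ties get half credit, and
`A(x,y) + A(y,x) = 1` exactly. Orientation is fixed: water /
water-response / non-rewarded coded low, sucrose / sucrose-response /
rewarded coded high.

Significance is a two-tailed permutation test on `|A − 0.5|`:
`p = (1 + #{|A_perm − 0.5| ≥ |A_obs − 0.5|})/(n_perm + 1)`, default
`n_perm = 10,000`. The same statistic serves all three contrasts; it is
equivalent to one-tailed tests on either side of the symmetric 0.4/0.6
thresholds. Permutation label shuffles are drawn once per neuron from a
counter-based split of the master seed and shared across that neuron's
bins; this lets the permuted auROCs of all bins be computed as a single
indicator-matrix × rank-matrix product per neuron, and makes serial and
parallel runs agree.

A bin **qualifies** when `p ≤ 0.05` and `|A − 0.5| ≥ 0.1`; for the
stimulus contrast it must additionally beat the choice-probability
companion `C` in the same direction (`A > C` when `A ≥ 0.6`, `A < C` when
`A ≤ 0.4`). A neuron is an encoder with ≥5 consecutive qualifying bins on
the 10 ms grid — overlap between windows is acknowledged and, as per the
screening design, no independence correction is applied; the run-length
rule is the guard. `best_bin` is the earliest maximum of `|A − 0.5|`
inside a qualifying run; preference is read from the sign structure of the
runs (both signs → switching).

**Trial sets.** The choice screen uses all trials labeled by response; the
outcome screen all non-aborted trials labeled by reward. The stimulus
screen computes `A` (stimulus labels) and `C` (response labels) **from the
same trial set including error trials**: on correct trials the two
labelings coincide trial-for-trial, so the disambiguation has content only
when errors are present. A correct-trials-only stimulus auROC remains
available for display via the `trials` argument.

**Known operating characteristics.** The consecutive-bin rule controls the
per-bin error at α but its neuron-level false-positive rate depends on the
auROC sampling spread: with ~100 balanced trials per class (SD of A ≈
0.04) the measured rate on untuned neurons is ~0; with a small minority
class (e.g. ~33 non-rewarded trials at the session's ~84% correct rate,
SD ≈ 0.055) the 0.1 margin sits < 2 SD from chance and the 90% window
overlap chains excursions into runs, giving a measured ~17% neuron-level
rate on the outcome contrast. This is a property of the rule itself at
those class sizes, not of its implementation; interpret outcome-encoder
counts accordingly.

The two-proportion z-test for comparing encoder proportions across regions
uses the pooled estimator `z = (p̂1 − p̂2)/√(p̂(1−p̂)(1/n1 + 1/n2))` with a
two-tailed normal p; a degenerate pooled proportion returns z = 0 with a
warning.

## Sequentiality

Over bins with centers in 0–800 ms post-alignment, the selectivity matrix
is rectified: `R = |A − 0.5|` where ≥ 0.1, else 0. Rows (neurons) with no
surviving activity are dropped.

- **PE** = `−Σ q_i ln q_i / ln(min(N, B))`, where `q` is the distribution
  of per-neuron peak bins (earliest bin on ties). Normalizing by the
  attainable maximum `ln(min(N, B))` — rather than `ln B` — matters when
  there are fewer neurons than bins: a population whose N peaks tile the
  epoch as evenly as N atoms allow then scores 1 instead of an
  artifactual `ln N / ln B` ceiling.
- **TS** = `1 − mean_b(H_b)/ln N`, with `H_b` the entropy of the activity
  shares `R[:, b]/ΣR[:, b]`; zero-total bins are excluded from the average
  (a zero column is not a distribution). `TS = 1` when each bin's encoding
  belongs to one neuron; 0 when all neurons share every bin equally.
- **SqI** = `√(PE·TS)`. The geometric mean is the combining rule uniquely
  consistent with the published (PE, TS, SqI) triples this package
  regression-tests, and preserves the [0, 1] range and the
  zero-annihilation property (either index at 0 forces SqI = 0).

Natural logarithms are used throughout; the normalizations make the base
irrelevant. Both entropies are clipped to [0, 1] against floating-point
overshoot. All three indices are invariant to positive rescaling of `R`.

**Split-half reproducibility.** Trials are split into two class-stratified
random halves (odd counts favor half 1), the auROC matrix is recomputed
per half, both matrices' rows are ordered by the first half's peak
latencies (cosmetic — the MSE is invariant to a common row permutation),
and the observed mean squared element-wise difference is compared with the
distribution over 10,000 row shuffles of the second matrix;
`p = (1 + #{MSE_null ≤ MSE_obs})/(n_perm + 1)`, small when row
correspondence (which neuron encodes when) reproduces across halves.
Latency distributions between populations are compared with the two-sample
Kolmogorov–Smirnov test on peak times.

## Decoding

Pseudo-trials homogenize neuron and trial counts: for each condition,
`T_c = 8` pseudo-trials are assembled, each neuron contributing the rate
of a trial drawn independently with replacement from its own trials of
that condition. Per sliding bin, a one-vs-one SVM (scikit-learn `SVC`;
linear, RBF, or degree-3 polynomial kernel; `C = 1`, `gamma="scale"` —
solver defaults, recorded in result metadata) is scored by stratified
8-fold cross-validation (16 binary pseudo-trials → 2 per fold; 48
six-class → 6 per fold). The construction repeats over 15 neuron samplings
(with replacement) × 10 trial samplings = 150 resamples; accuracy is the
resample mean ± SEM. The label-permutation arm shuffles labels before
folding in every resample and converges to 1/#classes. A fold missing a
class triggers refolding with a shifted seed (logged); with stratification
this is essentially unreachable.

Confusion matrices count out-of-fold predictions pooled over 300–840 ms
post-stimulus, row-normalized by true class; per-class accuracy is the
diagonal. The theoretical *fine* pattern is the 6×6 identity; the *gross*
pattern maps water → water and spreads each sucrose row uniformly (1/5)
over the five sucrose columns — the matrices a perfect six-way identifier
and a perfect categorizer-only would produce. Their mutual MSE is
`5(0.8² + 4·0.2²)/36 = 1/9`.

The **extended population** adds neurons with a significant one-way ANOVA
(any stimulus-epoch bin, p ≤ 0.05) across the six concentrations on
correct trials, minus neurons flagged choice-encoding.

**Licking control.** Each trial's full lick train is warped
piecewise-linearly so every inter-lick interval lasts 140 ms (lick k ↦
k·140; a spike at fraction f through interval k ↦ (k+f)·140); spikes
outside [first lick, last lick] are discarded — extrapolated time has no
behavioral meaning. Neural (outcome-encoder) rates and the single-channel
lick rate, both in warped time aligned to warped feedback, are decoded
with the linear-kernel pipeline above; per-bin significance of the
accuracy difference is a two-sided bootstrap (10,000 resamples of the 150
per-resample accuracies per arm; p = twice the smaller tail around zero).

## Psychometrics and neurometrics

The psychometric fit is unweighted least squares of `f(c) = a·c^b` in
linear probability space (initialized from a log-log regression) on the
positive concentrations; c = 0 is excluded (0^b is degenerate) but
reported in the empirical curve. The absolute threshold is
`c* = (0.5/a)^{1/b}`, exactly satisfying `f(c*) = 0.5`. All-equal
probabilities raise an error (b unidentifiable). Both per-session fitting
and fitting of an averaged curve are possible since the fitter takes any
(concentration, probability) table.

Parameter recovery is validated at generative values inside the
identifiable regime (`a = 0.25, b = 0.35`): at the session defaults the
20% point falls into the lapse clip (0.953 → 0.95), which biases `b`
downward, and the binomial sampling error of an exponent as small as 0.16
at 10,000 trials exceeds a 5% relative band — censored or
noise-dominated parameters cannot be "recovered" at that tolerance by any
estimator.

The optimal firing-rate threshold search is exhaustive over midpoints of
adjacent sorted unique rates plus ±∞ (so one-class classifiers are
representable), in both directions (high → sucrose or low → sucrose);
ties resolve to the smallest threshold, high → sucrose first. Its accuracy
is therefore never below the majority-class prevalence. The neurometric
curve applies the fitted (θ, direction) to every trial and reports the
fraction classified "sucrose" per concentration; a perfectly choice-locked
neuron reproduces the session's empirical psychometric exactly.

## State space

Spike trains are convolved with a Gaussian kernel at 1 ms resolution and
averaged per neuron within condition. "20 ms width" is interpreted as
σ = 20 ms (not FWHM) — stated explicitly for reproducibility. Kernels are
truncated at epoch edges without renormalization, matching default
density-estimation behavior; away from edges each spike contributes unit
mass to within 10⁻³. Inclusion thresholds: ≥5 correct trials per condition
for the six-stimulus analysis, ≥2 for the 12-condition analyses.

The neurons × (time·conditions) matrix (condition-major columns) is
row-centered and the neuron-space covariance eigendecomposed — covariance
PCA, no variance scaling. Projections reshaped per condition give
component × time trajectories, smoothed with locally weighted regression
(span 0.1 of the epoch; configurable, 0 disables). Distances between
condition trajectories are Euclidean in the leading 3 components by
default (the plotted components; exact count exposed), averaged ± SEM over
the 5 water-sucrose pairs or all 15 stimulus pairs; distances are
invariant to orthogonal rotations of the retained subspace.

## Pipeline, determinism and problem sizes

`run_all` derives every stage's seed from the master seed via CRC-tagged
`SeedSequence` splits, echoes all thresholds into `report.json`, logs
every excluded neuron/trial with its reason, and is byte-deterministic
given a seed. Simulation-based tests run at deliberately modest sizes —
200-trial sessions, 100-neuron populations, screens at 500–2,000
permutations where only a 0.05 threshold must be resolved, decoding on
bin subsets — chosen so each estimator is exercised at realistic power
without inflating the suite; the full 10,000-permutation defaults remain
the analysis defaults.

## Known limitations

- The auROC screen assumes exchangeable trials; slow rate drift would
  inflate encoder counts (no drift correction is implemented).
- The consecutive-bin rule's neuron-level false-positive rate grows with
  class imbalance (see Encoding screen); outcome-encoder proportions are
  upper bounds under strongly imbalanced sessions.
- Choice and outcome screens do not disambiguate against each other or
  against stimulus; only the stimulus screen carries a companion index.
- The lick warp discards spikes outside the lick train, so warped
  decoding is uninformative beyond the licking period.
- PE/TS depend on the encoder subset entering the rectified matrix;
  comparisons across populations of very different size should rely on
  the split-half and KS machinery rather than raw index differences.
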