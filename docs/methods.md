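# Methods

This note documents the models, conventions and numerical choices behind
`motorage`, in the spirit of a statistical package's model documentation:
what is computed, under which assumptions, which knobs matter, and what the
synthetic data can and cannot establish.

## Signal model and preprocessing

Each trial is a 3-axis stream from one of six sensors (accelerometer,
gyroscope, magnetometer at two placements) sampled at `fs = 50` Hz.
Preprocessing is per axis: 5th-order Butterworth band-pass 1–16 Hz, then
mean removal; the resultant magnitude √(s_x²+s_y²+s_z²) of the three
processed axes is the series all features are computed on.

Choices the literature leaves open, fixed here:

* **Zero-phase filtering** (forward–backward, `sosfiltfilt`) is the
  default: feature extraction cares about waveform shape, not latency.
  The effective attenuation is therefore that of a 10th-order filter.  A
  causal single-pass mode is available (`zero_phase=False`).
* **Order of operations**: filter → per-axis mean removal → resultant.
  The resultant itself is *not* re-detrended — its mean is a genuine
  amplitude property.  A `detrend_resultant` flag exists for sensitivity
  analysis.
* **No edge trimming.**  At ≥ 5 s × 50 Hz the filter transients are
  negligible relative to trial length.

## The 18 parameters

Amplitude: MAV, MAVFD, MAVSD (mean absolute value and of first/second
differences), RMS, Peak (maximum over *positive* samples; 0 with a warning
if no sample is positive).  Frequency: ZC (strict sign changes — exact
zeros never count), FMean = ΣPf/ΣP, FPeak, F50, F80 (first grid frequency
where cumulative power reaches 50%/80% — grid-anchored, no interpolation),
and band power over 3.5–7.5 Hz (the physiological-tremor band).
Statistics: VAR, RANGE, INTQ, SKEWNESS, KURTOSIS.  Entropy: ApEn, FuzzyEn.

Conventions (all switchable on `ParamConfig`):

* **VAR is the raw sum of squared deviations** (no 1/N).  Downstream
  min-max normalization makes the scale irrelevant; the literal formula is
  kept because it is testable.  `variance_mode="sample"` gives /(N−1).
* **Skewness/kurtosis use the population SD** (`bias=True`); kurtosis is
  Pearson (not excess).
* **Quartiles interpolate linearly** between order statistics (NumPy's
  default percentile rule), so for (1..8): Q1 = 2.75, Q3 = 6.25.
* **PSD**: Welch with Hann window, 256-sample segments, 50% overlap by
  default; a plain periodogram is available and is what the test oracles
  use (a pure tone at a grid frequency then lands in a single bin).
* **ApEn** (m = 2, r = 0.2·SD, Chebyshev distance): the correlation sums
  *include* self-matches, exactly as the printed counting rule implies,
  which keeps every log argument positive.  ApEn of a constant series is
  defined as 0.
* **FuzzyEn** (m = 2, r = 0.2·SD): template vectors are mean-centred,
  self-matches are excluded, and both window lengths use the same N−m
  templates, the standard construction.  The membership function is
  `exp(−(d/r)^gradient)` with gradient 2.  Normalizing d by r *before*
  exponentiation is deliberate: it makes FuzzyEn exactly invariant under
  signal rescaling when r is SD-relative, a property the test suite
  asserts.  (The variant `exp(−d^g/r)` is the same function with r
  reinterpreted as r^g, but is not scale-invariant for g ≠ 1.)

Entropies are computed from a shared pairwise-difference matrix with the
Chebyshev distance accumulated over shifted diagonals, avoiding the
(N,N,m) embedding tensor; this is an exact rewrite, verified against
naive triple-loop oracles to 1e−10.

## Reduction

Outlier fences are Tukey's Q1 − 1.5·IQR / Q3 + 1.5·IQR, computed **per
feature within each age group** at the trial level, so a genuine age trend
is not flagged as anomalous.  Flagged values are winsorized to the nearest
fence by default — the projection stage needs complete rows — with a
`drop` mode that excludes them from the trial average instead (empty cells
are then group-median imputed with a warning).  Trials are averaged per
participant, and redundant columns are removed by a greedy scan in
canonical (parameter, sensor, task) order: a later column correlating with
a kept column at **|r| > 0.9** is dropped.  The absolute value is used —
anti-correlated features are equally redundant — and keep-first ordering
makes the result deterministic and auditable.  Constant columns are
removed first.  The post-pruning matrix is asserted to contain no pair
with |r| > 0.9.

## The LDA-value and its optimization

Columns are min-max normalized to [0, 1] and offset by +0.1 so every entry
is strictly positive; each participant's vector is then represented by its
radius p and n−1 angles θ_k = arctan(c_{k+1}/‖c_1..c_k‖), and projected as
p·∏cos(θ_k + θ̂_k).  The identity p·∏cos(θ_k) = c₁ (θ̂ = 0) holds to
1e−9 and anchors the representation tests.

The separability E_z sums |x̄_i − x̄_j|/√(σ²_i + σ²_j) over all unordered
group pairs, with **population variances** and the denominator floored at
`ez_epsilon = 1e−12` for degenerate zero-variance pairs.  E_z is invariant
to adding a constant to all projections and scales by |a| under
multiplication — it measures ordering, not location or sign.

The GA (production defaults: 50 000 epochs, 50 axes, p_mutation 0.1,
p_crossover 0.8) works on angle vectors wrapped to [0, 2π):

* roulette-wheel selection proportional to E_z (uniform fallback when all
  fitness values are 0);
* the selected matrix is traversed in consecutive pairs; each pair
  produces three arithmetic children 1.5p₁−0.5p₂, (p₁+p₂)/2,
  −0.5p₁+1.5p₂; with probability p_crossover the two best children (by
  E_z) replace the pair, otherwise the parents pass through; an odd last
  individual passes through;
* per-gene mutation to a fresh uniform angle with probability p_mutation;
* **elitism**: the best axis ever seen replaces the generation's worst
  individual.  Elitism is an implementation choice: the method's output is
  "the axis with the highest E_z", and without re-injection that axis need
  not survive stochastic selection; the global best is tracked regardless,
  so elitism only accelerates convergence and makes the best-so-far trace
  monotone (asserted in tests).

Fitness evaluation is vectorized: a stack of axes is projected onto all
participants in one broadcastized cosine product, and children of all
crossing pairs are evaluated as one batch.

**Relevance filtering**: after the first GA pass, feature k's relevance is
|E_z(all) − E_z(feature k held at its column mean)| / E_z(all) — mean
substitution removes the feature's variation without changing the
dimensionality mid-axis.  Features below 1% relevance are dropped, the
hyperspherical representation is recomputed on the survivors, and the GA
is re-run on the reduced space; the final axis and per-participant
LDA-values come from this second pass.  If nothing clears the threshold,
the single most relevant feature is kept (with a warning); if only one
feature survives, the full set is retained since one feature has no
angular representation.

**Orientation**: E_z is blind to the sign of the projection, so the
reported LDA-values are flipped, if necessary, to increase with group
index (groups are ordered by age).  The flip is a reporting convention
recorded in `results.sign`.

**The published axis**: the original study's final model is a 46-feature,
46-offset cosine product; the offsets are shipped verbatim as constants
(`PUBLISHED_AXIS`) for scoring new data, including one offset (8.73)
outside [0, 2π) and five negative ones, transcribed literally.  Note the
printed equation pairs 46 features with 46 angles although n features
define n−1 angles; the evaluator follows the printed form and expects 46
angles.  The letter-to-sensor assignment of the published feature table is
not fully recoverable from its layout, so `feature_info` maps letters to
(task, parameter) only.

## Group statistics

Shapiro–Wilk per (feature, group) justifies the nonparametric route;
young-vs-elderly screening pools groups 1–4 vs 5–8 (the WHO split at 60
years) and applies two-sided Mann–Whitney per feature at α = 0.05
**without** multiplicity correction — the screen mirrors per-feature
reporting practice; a corrected mode can be layered on by the caller.
The LDA-value is compared across all 8 groups with Kruskal–Wallis followed
by pairwise two-sided Mann–Whitney, Bonferroni-corrected by the number of
pairs (28 for 8 groups, capped at 1).  All-tied features get p = 1 with a
warning.  The tally rules (a–g) count significant features per parameter,
parameter family (amplitude/frequency/entropy/statistics, with
proportions), task, sensor, sensor type (A1+A2, G1+G2, M1+M2) and IMU
(A1+G1+M1 forearm vs A2+G2+M2 hand).

## Synthetic cohort

The generator reproduces the study's design — 99 participants in eight
decade-band groups of sizes (13, 12, 13, 15, 11, 14, 13, 8) with the
published age means/SDs (truncated Gaussians per decade band), 3 tasks ×
3 trials × 6 sensors at 50 Hz — and embeds an age effect the pipeline
should recover:

* accelerometer/gyroscope streams are a tremor-band oscillation
  (f₀ ~ N(5, 0.5) Hz, axis weights 0.8/0.55/0.3) plus white noise; task
  multipliers 0.8 (rest), 1.2 (pinch), 1.0, with an extra 1.2–1.4 Hz
  voluntary component in task 3;
* tremor amplitude and the noise-to-signal ratio both drift linearly with
  age: gain 1 + slope·(age − 20) with slope 0.015/yr — roughly a doubling
  from age 20 to 90, a magnitude consistent with reported age trends in
  physiological tremor — on a baseline noise-to-signal ratio of 0.3;
  between-participant variation is lognormal with σ = 0.15;
* magnetometers are slow drift (~0.2 Hz) plus noise with the age effect
  attenuated ×0.3, reflecting their weak discriminative role;
* trial duration defaults to 10 s (the protocol required ≥ 5 s; 10 s gives
  the Welch estimator two full 256-sample segments);
* optional contamination amplifies whole trials ×8 with probability
  ≤ 0.1, and the feature-level generator can append near-duplicate
  columns (|r| > 0.9) and cell-level extremes beyond the IQR fences — all
  injections are recorded in a ground-truth registry so recovery (flag
  recall, pruning, relevance) can be scored, not eyeballed.

The feature-level shortcut generator (`simulate_feature_matrix`) draws
μ_j + γ_j·(age − 20) + ε directly, with a configurable affected fraction
(default 0.35) and random slope signs; it exists so the projection and
statistics layers can be tested without signal synthesis.

What the synthetic data does **not** emulate: real hand kinematics,
sensor-fusion artifacts, gravity leakage, task-specific biomechanics,
nonlinear or non-monotone aging, and between-feature correlation
structure beyond what the common carrier induces.  Passing tests
therefore demonstrate that the pipeline recovers a *linear, monotone*
age effect embedded in oscillatory signals under realistic noise — not
that it would achieve the same correlation on clinical data.

## Problem sizes and runtime choices

The package's canonical evaluation uses the full 99-participant cohort,
10 s trials, and 2000 GA epochs (not the production 50 000): on this
problem the best-so-far E_z is flat well before 2000 generations, and the
complete signal-level pipeline then runs in a few minutes on one CPU.
Unit tests use scaled-down cohorts (e.g. 4 per group, 5–6 s trials) and
short GA runs; the GA-vs-grid-search oracle uses a 2-feature problem
where the 0.1°-grid optimum is computable exactly.

## Known limitations

* The LDA-value's absolute scale shrinks exponentially with the number of
  features (a product of many cosines); only ordering and linearity are
  interpretable.  Comparisons across fits with different feature counts
  are not meaningful.
* The GA is stochastic; different seeds can land on axes of slightly
  different E_z (the acceptance-level correlation varies by a few
  hundredths across cohort seeds).
* Relevance is measured against the *first-pass* axis; features relevant
  only in interaction with a re-optimized axis can be discarded.
* With n features the representation has n−1 angles, so the first column
  in canonical order plays a distinguished role (it has no own angle);
  this mirrors the method's definition.
* The published 46-offset axis can score new 46-feature data, but the
  exact feature-to-letter-to-sensor assignment of the original model is
  underdetermined by the published table.
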