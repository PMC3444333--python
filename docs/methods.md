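# Methods

## Model and procedure

The object of study is the adaptive two-stage analysis of two independent,
equal-sized samples. Stage one tests the normality assumption with the
Shapiro-Wilk test at level α_pre; stage two tests equality of the group
locations at two-sided level α (default .05) with either the
pooled-variance t test (pretest not significant) or the Mann-Whitney U
test (pretest significant). Two gating strategies are implemented:

* **Strategy I** applies the pretest to each raw sample; the t branch
  requires both to pass. Under exact normality the U branch is taken with
  probability 1 − (1 − α_pre)² (two independent pretests).
* **Strategy II** applies one pretest to the collapsed within-group
  residuals (x_i − m_X), (y_i − m_Y) — the linear-model view, in which
  normality is a property of the error term. Its failure probability under
  normality is only approximately α_pre because the two centered halves
  are weakly dependent.

Conventions, fixed once and used everywhere: "pass" means pretest
p ≥ α_pre; every decision is "reject iff p < α" (strict). With continuous
data the boundary has probability zero, so only the consistency matters.

## Component tests

* **Pooled t** — T = (m_X − m_Y)/(s√(1/n_X + 1/n_Y)) with the pooled
  standard deviation s and n_X + n_Y − 2 degrees of freedom; p-values from
  scipy's t distribution. A constant pooled sample raises a typed
  degenerate-input error rather than returning NaN.
* **Mann-Whitney U** — U = #{x_i > y_j} + ½#{x_i = y_j}, computed from
  midranks. `mode="auto"` mirrors the default of R's `wilcox.test`: exact
  permutation distribution when the pooled sample is tie-free and smaller
  than 50, otherwise a normal approximation with tie-corrected variance
  and continuity correction. The exact null pmf is built by the standard
  count recursion and cached per (m, n); the two-sided p is
  min(1, 2·min(P(U ≤ u), P(U ≥ u))). Ties force the approximation (with a
  logged notice) because the tabled exact distribution assumes continuity.
* **Shapiro-Wilk** — Royston's AS R94 approximation (weights from expected
  normal order statistics with the two polynomial end-corrections;
  p-values via the n-dependent normalizing transformation of log(1 − W),
  exact for n = 3), implemented as a batch kernel that evaluates a whole
  (B, n) matrix at once and validated against `scipy.stats.shapiro`
  (agreement ~1e-9 on W; the test suite requires 1e-4). Supported sizes
  3 ≤ n ≤ 5000. The in-house kernel exists for throughput: the hardest
  conditional cell accepts ~1 pair in 60,000, and scalar per-sample calls
  would make rejection sampling there infeasible.

A known discreteness fact: at n = 10 per group the exact U test's attained
size at nominal α = .05 is .04326 (computed from the exact pmf), so "the
test rejects at rate α" is only meaningful for the continuous-statistic
branches; the calibration tests assert the attained size for the exact
branch and nominal α elsewhere.

## Monte-Carlo engine

Scenarios are frozen dataclasses; the estimators are pure functions of
them.

* **Conditional rates** use rejection sampling: generate pairs in batches,
  apply the pretest vectorized, keep pairs whose outcome matches the
  conditioning event until `reps` are kept, then run the branch's main
  test on the kept pairs. `attempts` counts generated pairs up to and
  including the last kept one, so `reps/attempts` estimates the pretest
  pass (or fail) probability — itself scientifically meaningful, and
  always logged.
* **Infeasible conditions**: if `max_attempts` (default 1000·reps) is
  exhausted first, a typed error reports the observed acceptance rate.
  Table reproduction converts these into "N/A" cells — the behavior of
  conditional-error tables at cells where the pretest essentially never
  passes. Note the default cap itself declares infeasible any cell with
  acceptance below 1/1000; the exponential/Strategy-II cell at n = 50,
  α_pre = .005 (acceptance ≈ 1.6e-5) is genuinely feasible and is run by
  the acceptance script with an explicit larger `max_attempts`.
* **Unconditional rates and power** analyze every generated pair with the
  full two-stage procedure (or a forced single branch for "t test only" /
  "U test only" rows); power is the same estimator under a shifted
  alternative.

**Randomness.** Each scenario's generator seeds from
SeedSequence(root seed, SHA-256(scenario key)), so scenarios are
order-independent and individually reproducible; the key excludes `reps`,
so enlarging a run extends the same stream. Pairs are drawn batch by
batch (default 20,000), making `batch_size` part of the stream layout;
it is a config field, and identical (config, seed) always reproduce
bit-identical results. No variance-reduction devices are used — estimates
are plain proportions with standard error √(p(1−p)/reps).

## Study conditions and defaults

Null populations: exponential with unit rate (unit mean and variance),
uniform on [0, 1], standard normal — skewed, short-tailed, and reference
shapes. Alternatives: exponential rates 1.0 vs 2.0, uniform [0, 1] vs
[0.2, 1.2], normal means 0.0 vs 0.6 at unit variance. Per-group sizes
10–50, α_pre ∈ {.100, .050, .010, .005}, α = .05. Replicate defaults are
10,000 conditioned pairs for conditional cells and 100,000 pairs for
unconditional and power cells, with a `reps_scale` knob for desk-speed
runs. The acceptance script reduces only the conditioned counts of the
rare-acceptance cells (to 1,000–5,000 kept pairs, as documented per
target), which widens their Monte-Carlo tolerance accordingly; its full
run takes ≈5 minutes on one CPU.

## What the generator does and does not emulate

The synthetic populations are the three idealized shapes above; real
clinical measurements bring ties from rounding, unequal group sizes,
variance heterogeneity and outlier contamination, none of which are part
of the study conditions (ties are *handled* by the U test via midranks,
but the generators are continuous, so tie handling is exercised only by
unit tests). Passing results therefore demonstrate the selection
mechanism of preliminary normality testing under clean sampling, not the
behavior of the procedure on any particular real dataset.

## Numerical and design choices

* The exact U table and the Shapiro-Wilk coefficient vectors are cached
  per sample size; all heavy loops are numpy-vectorized.
* The U p-value convention follows the R-default design choice above.
  Published n = 10 U-branch rates (~.050–.053 on null data without any
  pretest) are slightly above the exact test's attained size .0433,
  matching instead an uncorrected normal approximation; the difference is
  within the Monte-Carlo tolerances used here, and the R-default
  convention is kept.
* Uniform sampling uses the half-open [a, b) generator; the boundary has
  probability zero, so closed vs half-open is immaterial.
* Scenario results serialize to tidy CSV/JSON (one row per cell: rate,
  mc_se, reps, attempts, acceptance_rate, note), and tables render to a
  Markdown grid with one block per distribution and one column per n;
  numbers are displayed to 3 decimals but kept at full precision in files.

## Limitations

Equal group sizes only; no variance-homogeneity pretest or Welch-type
branch; no Cauchy or other heavy-tailed families; exact-U conditional
inference under ties is out of scope (approximation is used); agreement
with reference estimates from other implementations of the same study
conditions is at Monte-Carlo tolerance, since random streams differ.
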