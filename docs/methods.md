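# Methods

## The problem

Causal forests and related CATE (conditional average treatment effect)
estimators are usually validated in simulations where treatment assignment
is ignorable given the measured covariates.  In observational clinical
data, the decision maker often knows more about a patient's likely benefit
than the researcher can measure, and treats accordingly — *essential
heterogeneity*, or "sorting on the gain".  `sortgain` provides a generative
model in which the strength of that sorting is a single dial, plus the
estimators and diagnostics needed to measure what it does to
patient-specific effect estimates.

## Generative model

Per patient i:

- six binary effect modifiers `x1..x6 ~ Bernoulli(0.5)`, independent;
- true treatment effect `TE_i = Σ_k β_k x_ki` with default increments
  β = (.024, .048, .071, .095, .119, .143) (absolute risk units).  Over the
  64 equiprobable factor cells TE ranges over [0, 0.5] with mean exactly
  Σβ/2 = 0.25 (computed by exact enumeration, `enumerate_te_distribution`);
- severity `S_i ~ Uniform(−.5, .5)`, affecting cure but never choice;
- the decision maker's expected effect
  `ETE_i = K·(TE_i − Σβ/2) + Σβ/2`, an affine shrinkage of the truth
  toward the population mean controlled by the knowledge share K ∈ [0, 1];
- expected value of treatment `EVT_i = V·ETE_i − C + U_i` with cure value
  V = $800, treatment cost C = $200 and valuation noise
  `U_i ~ N(0, σ_U²)`; the patient is treated iff `EVT_i > 0` (an exact
  zero — probability zero under continuous noise — resolves to watchful
  waiting);
- cure probability `p_i = α_0 + α_S·S_i + TE_i·T_i` with α_0 = 0.1 and
  α_S = −0.1, hence p ∈ [.05, .15] untreated and [.05, .65] treated; the
  binary outcome is a Bernoulli draw from p_i.  Parameter combinations
  that could push p outside [0, 1] are rejected at configuration time
  rather than clamped.

At K = 0 the only source of choice variation is U, so treatment is
independent of both potential outcomes (ignorability).  V = C ·… at the
mean patient `EVT = 800·0.25 − 200 = 0`, which pins the treated share at
50% for every K by the symmetry of the TE distribution.

Randomness uses one master seed per scenario with independent substreams
for factors, severity, valuation noise and outcomes, so changing e.g. the
noise scale leaves every other component's draws bit-identical.

## Calibrating the valuation-noise scale

σ_U is the one parameter without a defensible a-priori value; what matters
scientifically is how much choice variance the true effect explains.  The
package therefore calibrates σ_U so that, at K = 1, the R² of an OLS of T
on TE equals a target share — 0.48 by default, the strongest sorting
condition studied.  `calibrate_noise_sd` scans a grid (default $30–$100 in
$0.50 steps) with common random numbers, so the R² is monotone in the
candidate and the grid argmin is deterministic given the seed; it lands
near $59.  With that scale the mean true effect is ≈ .329 among treated
and ≈ .172 among untreated patients at K = 1, and under full observation
the overlapped share falls to ≈ 69%, while under partial observation
(only x1..x4 observed) everyone stays overlapped.

## Diagnostics and parametric benchmarks

- *Propensity/overlap*: unpenalized main-effects logit of T on the
  observed factor set (severity is excluded by default because choice is
  generated independently of it; it can be added via the covariate
  matrix).  If the likelihood separates — some factor cell
  deterministically treated — maximum-likelihood logits diverge, and the
  model falls back to empirical per-cell treatment frequencies, which is
  deterministic and exactly right for degenerate cells.  Separation is
  detected by non-convergence or a coefficient magnitude above 15
  (cell odds beyond e¹⁵).  A patient "overlaps" iff the fitted score is
  strictly inside (0.05, 0.95); boundary hits count as non-overlap.
- *Choice-variance share*: R² of an OLS of T on TE, reported in percent
  (with a single regressor this equals the squared semipartial
  correlation).
- *ATT benchmark*: linear probability model of Y on (1, T, S); under the
  choice model the T coefficient consistently estimates the mean true
  effect among the treated, so the sweep asserts
  |ATT − mean TE(treated)| ≤ 3 binomial-scale MC standard errors in every
  scenario.

## Honest causal forest

A from-scratch generalized-random-forest-style estimator:

- per tree, a 25% subsample is drawn without replacement and divided
  50/50 into a *split half* and an *estimation half* (both fractions are
  parameters);
- splits maximize `n_L n_R/(n_L+n_R)² (τ_L − τ_R)²` over all features and
  midpoint thresholds, where τ is the child's treated-minus-control mean
  outcome; children must have at least `min_leaf` split-half rows
  (default 50) and both arms non-empty; growth stops when no feasible
  split has a strictly positive score;
- honesty: leaf effects are re-estimated from the estimation half only;
  leaves whose estimation sample is single-armed are unusable (NaN)
  rather than merged — simple, testable semantics;
- predictions average usable leaf effects over trees; out-of-bag
  prediction uses only trees whose subsample excluded the patient;
- no local centering of Y or T by default: treatment is unconfounded by
  construction in every scenario (valuation noise ⊥ outcome residual,
  severity not in the choice rule), so difference-in-means leaves are
  consistent; a `center_outcomes` hook accepts a user-supplied outcome
  model if residualization is wanted;
- all features are considered at every split (`features_per_split="all"`):
  with at most 7 features, random feature subsetting would only add
  variance.

The split search was validated against exhaustive enumeration of every
feasible (feature, threshold) pair on small fixtures, and honesty by
poisoning the split half's outcomes and checking leaf estimates only ever
reflect the estimation half.

No numerical parity with any particular published forest implementation
is attempted; the evaluation surface is sign, magnitude and monotonicity
of subset biases, which are implementation-robust.

## Evaluation surface

For each K in the 11-point grid {0, .1, …, 1} one population is simulated
and reused for both observed-factor sets ("full": x1..x6 + S; "partial":
x1..x4 + S), so every patient gets two out-of-bag effect estimates.  Bias
per subset (full population; treated/untreated; the four
treatment × overlap cells) is the *signed* mean of (estimate − truth) on
the absolute-risk scale — signed, because the interesting failures are
directional — and as a percentage of the subset's mean *true* effect.
Undefined estimates (patients no usable tree covers) are excluded and
counted.  Report files round effect scales to 3 decimals and percentages
to 2.

Expected signatures, asserted by the test suite:

- K = 0, either observation set: all subset biases statistically
  indistinguishable from zero (ignorability recovered);
- partial observation, K ≥ 0.3: treated-subset bias stays near zero while
  untreated-subset percentage bias is positive and grows with K — the
  estimates align with the patients a decision maker would actually
  treat;
- full observation, K → 1: untreated bias turns positive as common
  support erodes, and the *non-overlapped* treated patients are estimated
  below the truth (pooling pulls extreme cells inward).  The
  population-level treated-subset bias, however, stays near zero for this
  estimator: the honest difference-in-means leaves remain approximately
  unbiased wherever even a few controls reach a leaf, and the negative
  non-overlap component nearly cancels against the overlapped remainder.
  Reference implementations that residualize outcome and treatment on
  covariates before splitting behave differently in near-deterministic
  cells — after centering, a patient whose cell is almost always treated
  carries no identifying variation, so the estimate comes entirely from
  pooled neighbors and the treated subset drifts markedly below the
  truth.  This package's default deliberately omits that centering (see
  above), so only the non-overlap component of the full-observation
  treated signature is expected here.

## Problem sizes and numerical choices

Two presets: `paper` (n = 50,000 patients, 4,000 trees) and `desk`
(n = 10,000, 500 trees), the package default.  The test-suite sweeps run
at n = 25,000 with 150 trees — chosen so subset-bias Monte-Carlo noise
(≈ 2pp on the percentage scale, dominated by outcome Bernoulli noise
rather than tree count) is well below the asserted signatures.

The mean percentage bias of a single desk-scale run under ignorability
has a Monte-Carlo standard deviation of ≈ 3.4pp (measured over 96
replicate populations), so zero-bias checks at a ±2pp tolerance average
the percentage difference over independent replicate populations
(24 replicates × n = 10,000 × 250 trees; standard error ≈ 0.7pp) instead
of trusting one draw.

Ties and degenerate cases: the split argmax keeps the first-scanned
maximizer (features in index order, thresholds ascending); binary factors
contribute the single threshold 0.5; an empty subset reports NaN, never a
silent 0; a forest prediction with no usable tree is NaN and excluded
(with a count) from bias summaries.

## What the generator does and does not emulate

It emulates: discrete effect modifiers with known ground-truth effects,
value-based treatment choice with tunable knowledge, unconfounded noise,
and a severity covariate that affects outcomes only.  It does not emulate
continuous or correlated effect modifiers, confounding through severity,
time-to-event outcomes, measurement error in Y, or decision makers whose
valuation noise correlates with outcomes.  Passing tests therefore show
how estimators behave under pure, cleanly-dialed sorting on the gain —
not that they are safe under arbitrary real-world confounding.

## Known limitations

- Leaf estimates carry no uncertainty quantification (no bootstrap or
  jackknife variance); the evaluation is of point-estimate bias only.
- The separation fallback abandons the logit model entirely rather than
  using penalized likelihood; with factor-only covariates the cell
  frequencies are the saturated-model answer, but with continuous
  covariates the fallback would coarsen severely (not a configuration the
  package generates).
- The calibration targets a single scenario (K = 1); no single σ_U was
  found that makes the choice-variance share match a prescribed sequence
  across *all* K simultaneously, and none is claimed.
- Without local centering the forest does not reproduce a
  population-level *negative* treated-subset bias under full observation
  and strong sorting; that behavior is specific to orthogonalized leaf
  estimators.  The `center_outcomes` hook exists for experimenting with
  residualized outcomes, but full treatment-and-outcome
  orthogonalization (with its covariance-ratio leaf estimator) is not
  implemented.
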