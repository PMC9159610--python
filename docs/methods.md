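# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `ddmeta`, at the level of detail a user
needs to judge what the package's results do and do not show.

## Trial model and preprocessing

The atomic unit is one behavioural trial (subject, group, task, condition
factors, binary response, correctness, RT in seconds, ordinal confidence
rating).  RTs are stored in seconds internally; files recorded in
milliseconds can declare `rt_unit="ms"` at load time.

Preprocessing applies three filters, in a fixed order:

1. **RT floor** (default 0.200 s): anticipations cannot carry stimulus
   information.
2. **Choice reversals** (interrogation task only): ratings at the reversal
   key (below-50% confidence) signal a changed mind, not a graded confidence;
   they are removed when `drop_reversals` is set.
3. **SD outliers** (default 3 SD, two-sided, per subject × condition),
   computed on trials surviving steps 1–2 so the mean and SD are not
   contaminated by anticipations or reversals.

The rule is two-sided although only the slow side is usually active — the RT
floor already handles fast guesses — because an asymmetric rule would need a
justification the data do not provide.  The rule is applied to all trials,
not correct trials only.  The filter log counts removals per rule and always
sums to the input/output difference; the filters are idempotent.  The lowest
confidence level of the 6-point scale ("50%") is kept at face value even
though subjects occasionally use it to signal certainty of an error; the
package flags nothing and recodes nothing, leaving any reinterpretation to
the analyst.

## Wiener first-passage machinery

The 4-parameter DDM (drift `v`, boundary separation `a`, relative start
`z`, non-decision time `Ter`; unit diffusion) is the only RT model.
Inter-trial variability parameters (sv, sz, st) are deliberately absent:
the model space is defined over the four core parameters, and adding
variabilities would change the enumerated 8/16/7 model counts.

* **Density.** The defective first-passage density uses the classical dual
  series: the large-time (sine) expansion and the small-time (image) sum,
  choosing per evaluation whichever needs fewer terms for an absolute error
  below 1e−7.  Probability is conserved to 1e−6 (checked by quadrature), and
  the closed-form absorption probability
  `(1 − e^{−2vza}) / (1 − e^{−2va})` (→ `z` as `v → 0`) serves as an
  independent oracle for both density and simulator.
* **Simulator.** Euler–Maruyama with step `dt = 1e−3 s` plus an exact
  Brownian-bridge absorption test inside each step (crossing probability
  `exp(−2(a−x)(a−x′)/dt)` per boundary).  The bridge test removes the
  O(√dt) boundary-detection bias of naive Euler; the remaining discrepancy
  from the analytic density is below 0.005 Kolmogorov–Smirnov at 10⁵ trials.
  The simulator never uses the series density, so simulator/likelihood
  agreement is a genuine two-route check.
* **Censoring.** Free-response tasks have deadlines (1.5 s / 1.25 s).
  Censored trials are flagged by the simulator and excluded from the
  likelihood with a logged count rather than modelled by a truncated
  density.  This is the main known limitation of the fitting stage: with
  heavy censoring (slow subjects under a tight deadline) thresholds are
  biased downward, and the parameter-recovery guarantees below are stated
  for censoring-free data.

## Hierarchical estimation

Subject parameters live on unconstrained scales — `v` raw, `log a`,
`logit z`, `log Ter` — and are partially pooled:
`θ_sj ~ Normal(μ_j + δ_j·g_s, σ_j)` with `g_s = ±1/2` group coding.  Priors
are weakly informative on those scales: group means
Normal(0.5, 2) for drift, Normal(log 1.5, 0.5) for log-threshold,
Normal(0, 0.7) for logit-start, Normal(log 0.3, 0.5) for log-non-decision
time; group SDs half-Normal (scales 0.5/0.3/0.5/0.3); group offsets δ
Normal(0, 1).  All are overridable in code; they are broad enough that the
recovery studies are insensitive to doubling any prior SD.

The sampler is Metropolis-within-Gibbs, jit-compiled:

* per subject × parameter-slot random-walk updates, evaluating only the
  trials that depend on the slot, with per-slot proposal scales adapted
  during burn-in toward ~35% acceptance;
* conjugate Gibbs draws for group means and group offsets;
* a random walk on `log σ_j` with the half-Normal prior and log-Jacobian.

Defaults mirror the standard profile of 5 chains × 5000 samples with a
1000-sample burn-in; the test-suite and pipeline run reduced profiles
(2–3 chains × 700–2500 samples) chosen so each study finishes in seconds to
minutes while still passing its convergence criterion.  Convergence is the
classic Gelman–Rubin ratio per group-level parameter, floored at 1.0
(identical chains read exactly 1.0) with the conventional < 1.1 criterion;
the implementation is cross-checked against `arviz.rhat` in the tests.

**DIC.** `DIC = D̄ + p_D`, `p_D = D̄ − D(θ̄)`, where the deviance is the
trial likelihood conditional on subject-level parameters (the "focused"
deviance appropriate when subject parameters are the quantities of
interest) and `θ̄` is the posterior mean of the subject parameters.  A
degenerate zero-variance posterior sets `p_D = 0` with a warning.  DIC
estimates at short chains carry noise of a few points; the selection rule's
10-point threshold absorbs most of it, and the suite's replicated studies
quantify what remains.

**Posterior contrasts.** `P = mean(A_s > B_s)` over aligned samples, ties
counting one half (so `P(A>A) = .5` and `P(A>B) + P(B>A) = 1`), with
`P ≥ .95` flagged, the posterior analogue of a one-sided test.

**Posterior predictive checks** simulate each condition cell from random
posterior draws and compare observed accuracy and RT quantiles
(.1/.3/.5/.7/.9) against 95% predictive intervals.

## Model spaces and two-stage selection

Stage 1 (within-subject structure only, no group effects):

* speed/accuracy task: accuracy coding (upper boundary = correct), start
  point fixed at 1/2; `v`, `a`, `Ter` each constant or by emphasis → 8
  models;
* cued face/house task: stimulus coding (upper boundary = face), `z`
  constant or by cue, `v` constant/by cue/by stimulus/by both (full
  crossing), `Ter` constant or by cue → 16 models.  `z` never depends on the
  stimulus: the start point is set before the stimulus appears, and a
  stimulus-dependent start would imply prescience.  In fitted datasets the
  "cue" factor is the cue-congruency column of the trial table.

Stage 2 freezes the winning within-structure and adds the 7 non-empty
subsets of group effects on the three focus parameters.  The comparison
baseline is a *refit* of the no-trait model rather than the cached stage-1
value, so the verdict does not hinge on sampler noise between stages.  Ties
within the 10-point band resolve to the model with fewer free parameters
(parsimony), flagged as ties.  Fits whose worst R̂ reaches 1.1 are excluded
from selection with a warning — a guard that can occasionally exclude the
true model at very short chains, which is the main reason the pipeline's
demo profile uses 3 chains.

## Metacognition

Type-1 d′ and criterion use the log-linear (+0.5) count correction, keeping
both finite for perfect scores.  meta-d′ is single-subject maximum
likelihood on the 2×2×K table: every response-conditional rating probability
comes from an SDT observer with sensitivity meta-d′ whose type-1 criterion
is carried over scaled by meta-d′/d′; cells are padded by `1/(2K)`; the
optimizer is L-BFGS-B from five jittered starts on a parameterization that
enforces ordered type-2 criteria.  One meta-d′ is fitted per table (both
responses jointly), matching the common single-meta-d′ reporting
convention.  The estimator's contracts, all exercised in the tests: ideal
observers (ratings cut on the decision axis) recover meta-d′ = d′ within
0.05 at 5×10⁴ trials; read-out noise strictly lowers meta-d′; a global
rating shift moves it by < 0.1; M-ratio 0.7 is recovered within ±0.1
(median) at 3000 trials.

## Statistics

* **LISAS**: `L = meanRT_correct + PE · S_RT/S_PE` per subject × condition,
  with `S_RT` the SD of the subject's correct RTs and `S_PE` the SD of the
  binary error indicator, both pooled across the subject's conditions — so
  the error weight is a subject property, not a cell property.  A
  never-erring subject's score reduces to the mean correct RT, flagged.
* **Mixed ANOVA** (balanced designs, cell means per subject — aggregate-
  then-test): the cell space is rotated by a full orthonormal basis built
  from Kronecker products of per-factor orthonormal contrasts, which
  preserves sums of squares exactly, so each within-stratum F, the
  between-group F, and their error terms equal the classical univariate
  decomposition (verified against `pingouin` to machine precision on the
  shared one-within case, and against the two-sample t² identity).
  Greenhouse–Geisser ε comes from the pooled within-group covariance of
  each effect's contrast scores (ε = 1 exactly for 2-level factors);
  corrected p-values are reported alongside uncorrected degrees of freedom.
  Generalized η² follows Olejnik–Algina: effect SS over effect SS plus all
  subject-error SS.  Subjects with missing cells are dropped listwise with
  a warning.
* **Cronbach's α** by the variance-ratio formula; the Spearman–Brown
  equivalence at r = .49 (α ≈ .658) is a test oracle.
* **Power simulation**: per replicate, a fresh screening pool of combined
  scores, a latent variable `y = r·z(score) + √(1−r²)·ε`, bound-based
  extreme-group selection, and a two-sided Welch t-test.  Power is the raw
  rejection rate at α; the subtracted variant (rate − α) is reported as a
  separate column and never blended into the headline number, because
  subtracting false positives from power conflates two different
  quantities — both are given so either convention can be read off.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed and the
tests run against them.

* **Screening**: 724 respondents × 24 binary items from a one-factor model
  (endorsement .5, latent inter-item correlation .26).  These two constants
  imply a combined-score SD ≈ 5.2 and internal consistency α ≈ .85 —
  the realistic regime for a two-subscale combined trait score.  Extreme
  groups of 30 use the stated bounds (≥ 25 action / ≤ 6 state).  The action
  bound exceeds the 24-point scale maximum; the generator accepts it
  verbatim, clamps to 24 with a warning, and — since essentially nobody
  scores a perfect 24 — relaxes to the 30 most extreme scorers, again with a
  warning.  A subscale-median guard (both subscales on the proper side of
  their medians) is applied when feasible.  Realized group separation is
  ~2.8–3.4 pool SDs across seeds.
* **Subjects**: decision parameters come from one shared hyper-distribution
  (drift skill N(1, 0.15²) scaling task base drifts 0.45 (coherence-
  calibrated dot motion, ~65% correct) and 1.5 (easy face/house, ~90%);
  threshold N(1.6, 0.2²) with ±0.2 emphasis modulation; non-decision
  N(0.35, 0.05²) with ±0.04 emphasis modulation; start point N(.5, .04²)
  with ±0.08 cue modulation in the cued task).  Groups differ only in the
  confidence read-out: an additive percent-scale bias (action 20, state 14;
  gap 6 points) and optionally the read-out noise.
* **Confidence read-out**: on every trial the confidence system reads the
  magnitude of an SDT-consistent decision variable (sampled conditional on
  correctness at the condition's effective d′), adds Normal read-out noise
  (σ_m = 1, on the evidence scale) and the group bias, maps through a gain
  of 12 points per evidence unit, and thresholds midway between the scale's
  level values — a monotone map by construction.  The gain/bias defaults
  put the read-out mostly inside the 50–100 range so the configured bias
  gap survives thresholding (realized ~5.2–5.5 of the configured 6 points);
  read-outs below the bottom cut land on the lowest level, or on the
  reversal key for the 7-key interrogation scale.  With σ_m = 0 the
  read-out is the ideal observer (meta-d′ ≈ d′, up to rating
  discretization); σ_m → ∞ gives meta-d′ → 0.
* **Designs** are exact by construction: 3×54 dot-motion trials balanced
  over emphasis; 480 face/house trials in which two thirds carry an
  80%-valid cue and one third a neutral cue, with fixed counts giving
  exactly 256/64/160 congruent/incongruent/neutral (53.33/13.33/33.33%);
  160 interrogation trials using each sampled pair once, 20 per
  domain × difficulty × interval cell, counterbalanced over interval and
  display side.  Randomization permutes order only.
* **Interrogation trials** use an SDT evidence sample at the response beep
  (evidence ~ Normal(±d/2, 1)) rather than a boundary-crossing process:
  responses are cued at a fixed 2 s, so RTs are motor-dominated and a
  diffusion fit is neither intended nor meaningful there.  Discriminability
  is a compressive power function of the normalized value distance
  (`d = 3.6·(Δ/Δmax)^0.4`), the simplest map that simultaneously yields
  ~94% easy and ~70% difficult accuracy — a linear map cannot.  Long-
  interval trials average in a second, independent, choice-congruent
  evidence sample, which raises metacognitive sensitivity without moving
  the bias, supporting interval × difficulty analyses.
* **Item values** for the pair algorithm are drawn from
  Normal(42.05, 16.46²) truncated to [22.77, 90.05] (percent of image
  area), the regime in which both an easy and a difficult stratum of 40
  pairs exist for ≥ 95% of seeds.

What the generator does **not** emulate: sequential effects (post-error
slowing, cue-order effects), response-key biases, rating-scale idiosyncrasy
beyond a global bias, subject dropout, and any correlation between the
screening trait and decision parameters.  Green tests therefore certify the
*pipeline* — that each estimator recovers what the generative model planted
and that null effects stay null — not any empirical claim about real
populations.

## Problem sizes and determinism

Every stochastic stage takes an explicit seed, and a pipeline run is
reproducible byte-for-byte from config + seed (outputs embed a hash of the
scientific configuration).  The studies in the test suite use sizes chosen
as the smallest at which the property under test is clearly resolved:
recovery at 20 subjects × 200 trials; selection studies at 12 subjects ×
162 trials with 10 replicates; power at 10⁴ replicates; meta-d′ contracts
at 3×10³–5×10⁴ trials.  The acceptance script reports the power of the
extreme-group design at r = 0.3 and the closed-loop calibration accuracy,
both recomputed from scratch at 10⁴ replicates/trials.

## Known limitations

* Deadline censoring is handled by exclusion, not truncated likelihoods
  (see above); selection on heavily censored data needs longer chains and
  can exclude threshold-varying models via the R̂ guard at demo-scale
  profiles.
* DIC is the only model-comparison metric, by design; no bridge sampling or
  Bayes factors.
* The meta-d′ implementation is single-subject MLE only — no hierarchical
  variant — and fits one meta-d′ per table rather than response-specific
  values.
* The ANOVA handles balanced designs with one between-subject factor;
  unbalanced data are handled by listwise deletion only.
* The closed-loop calibration carries ~2 points of irreducible noise from
  estimating the psychometric slope on a 200-trial block; that is a
  property of the design being emulated, not of the estimator.
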