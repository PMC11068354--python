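# Methods notes

## Task environment

The biased-matching-pennies environment is parameterised by `TaskConfig`:

| parameter | default | meaning |
|---|---|---|
| `gain_tokens` / `loss_tokens` | 2 / 1 | tokens gained on a match / lost on an unlucky non-match; the P-like profile uses 1 / 2, the Y/B-like profiles 2 / 1 |
| `tokens_to_reward` | 6 | asset at which tokens exchange for juice |
| `free_tokens_range` | [2, 4] | uniform draw restarting the asset after juice |
| `block_length` / `block_switch_prob` | 40 / 0.1 | trials with fixed risky side; per-trial flip probability afterwards |
| `p_loss_risky` / `p_loss_safe` | 0.75 / 0.25 | probability that a non-match yields loss rather than neutral; only the ordering (risky > safe) is constrained by the task description, the exact values are a package default |
| `asset_floor` | 0 | tokens cannot go negative |

The computer opponent estimates P(choose right | history pattern) for every
pattern of the last 1–4 choices and of the last 1–4 choice-outcome pairs,
tests each against 0.5 with an exact binomial test at α = 0.05, and answers
the most significant bias by playing the side opposite to the predicted
choice.  The published task description is qualitative on this algorithm, so this
exploiter is a faithful-in-spirit stand-in and is configurable; a uniform opponent is also
provided and is used for fitting-oriented simulations, since likelihoods
condition on the observed history and are opponent-agnostic.  Notably, the
exploiter holds a DF-saline agent's gain rate well below the 0.5 matching
equilibrium (≈0.18 at the default settings) because the strongly
outcome-driven switching of that parameter set is highly predictable.

## Model family

All families share: value state initialised to Q(R) = Q(L) = 0 at every
session start (no carry-over across sessions), auxiliary traces initialised
to 0, and short history buffers that read 0 where fewer than four trials
exist.  β is a free parameter only in standard Q-learning; everywhere else
it is fixed at 1 because free Δ's absorb its scale.  Likelihood evaluation
clips single-trial choice probabilities at 1e−12.

Implementation notes on points where the printed model table is ambiguous:

* The perseveration indicator in K6/K7 refers to the **previous** trial's
  choice (the trial-t choice is not yet made when X_t is formed).
* The K10 gate is implemented as I(|rFreq_t| ≥ τ); with τ > 0 the strict
  and non-strict forms are almost-surely equivalent.
* K11's asset-gated update is implemented as one effective gain,
  λ · asset_t · Δ_t^S (a separate learning-rate factor would be absorbed
  into λ and is not separately identifiable).  The asset is the token count
  at decision time (`asset_pre`).
* Both DF-A and NDF-A asset-gated baseline variants exist (published
  accounts differ on which variant was tested); either can be fitted.

Two likelihood paths exist: a readable per-trial reference
(`session_nll`, built from `update_values` / `decision_variable` /
`choice_probability`) and a session-vectorised kernel (`pooled_nll`) used by
the fitter.  They agree to ~1e−12 on every family (tested), and both agree
with an independently coded history-based oracle in the test suite.

## Fitting

Sessions are pooled within animal × condition with per-session state resets;
BIC uses n = total modelled choices.  (Whether the original analysis pooled
sessions or fit them separately is not stated; pooling matches the
single-parameter-set-per-animal layout of the published estimate table.)
Optimisation is bounded L-BFGS-B with multi-start: one start at the centre
of the (clipped) box plus uniform random restarts, seeds recorded.  Bounds:
rates and mixture weights [0, 1], τ [0, 10], β (1e−3, 20], outcome updates
and shifts [−10, 10] (random starts clipped to [−3, 3]).  The restart
spread (max−min NLL over restarts) is reported; on the synthetic problems
used here it is ~1e−6, consistent with a unimodal likelihood.

Two-stage ketamine fitting freezes the converged saline DF estimates as the
K-model's baseline binding; only deviation parameters are optimised, and the
baseline values are carried bit-identically (tested).

## Synthetic studies

The generator emulates: per-animal saline/ketamine session sets with the
published session counts (52/17, 49/15, 25/9 for the P/Y/B-like profiles),
the per-animal payoff magnitudes, block structure and token dynamics, and a
step-function drug window — ketamine parameters apply 0–60 min
post-injection, saline parameters outside (the published time course peaks
and wanes within about an hour; a pharmacokinetic ramp is deliberately not
modelled).  Values not printed in the source material are package choices:
700 trials/session, 8 s/trial, sessions starting 20 min before injection.
It does **not** emulate eye movements, fixation breaks, aborted trials,
satiation, day-to-day carry-over, or plasma kinetics — so passing tests
validate the statistical machinery on idealised behavior, not those aspects
of real data.  Real sessions also differ in trial counts and pacing.

## Descriptive regressions

The lagged-outcome logistic fits include an intercept (real animals have
side biases; the original analysis reports none — coefficients are reported
either way).  The first `n_lags` trials of each session are dropped rather
than zero-padded, since zero-padding would fabricate "no outcome" events.
Condition contrasts are two-sided Wald tests on coefficient differences
with pooled standard errors, standing in for the published across-session
t-tests.  Exponential decay fits optimise the two branch time constants on
a positive box [0.01, 1000] (the ketamine modulation b1k is their
difference), keeping both branches well defined.

Time-resolved modulation uses 10-minute non-overlapping bins over −20…+80
minutes by default (the published figure's binning is not printed).  The
shuffle null permutes session-level condition labels; the output reports
the null mean and SE (the quantity the published figure plots as dotted
lines) and a 2.5–97.5 percentile band.  The calibration test checks that
null-study differences stay within null-mean ± 3 SE in ≥ 95% of bins — an
SE-multiple band is used there because an exact 95% percentile band would
by construction leave ~5% of null bins outside, making "≥ 95% inside" a
coin flip rather than a calibration check.

Switch-by-asset bins assets as {0–1, 2, 3, 4} and tests the
condition-by-asset interaction with a trial-level logistic regression.  On
full synthetic ketamine sessions this interaction can reach nominal
significance even without any asset coupling in the generator, because
ketamine parameters apply only inside the drug window and the asset
distribution co-varies with time in session; the null-calibration test
therefore uses studies whose two conditions are generated identically.

## Problem sizes

The acceptance script runs each recovery experiment at reduced scale
relative to the 100-session × 20-replicate design the tolerance analysis
was framed for: 40 sessions × 1,000 trials × 12 replicates for the DF
experiments and 24 × 1,000 × 10 for the K-model-4 experiments, with 4
optimizer restarts, against a uniform opponent.  At these sizes the
Monte-Carlo standard error of every reported median (measured from
replicate spread) is at least a factor of two below the corresponding
tolerance — the binding case is α_F-C, whose per-replicate sampling SD is
≈ 0.06 at 40k trials, giving a median SE ≈ 0.02 against a ±0.05 tolerance.
The test suite uses slightly smaller sizes again, chosen the same way.

## Known limitations

* The exploiting opponent is a reconstruction, not the original algorithm;
  absolute gain rates under it should not be over-interpreted.
* No standard errors are computed for RL parameter estimates (none are
  reported in the source analysis); recovery experiments quantify estimator
  spread instead.
* Aborted/no-choice trials are not generated; the fitter's exclusion path
  for them is exercised only via padding in the vectorised kernel.
* Hierarchical or Bayesian estimation across animals is out of scope.
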