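# Methods

## The model

One trial presents four intervals D₁…D₄ (ms) drawn from a fixed set with
mean 700 ms. The observer summarizes the sequence by an ensemble prior whose
mean weights the first interval against the design mean,

    μ_e = α·D₁ + 700·(1 − α),        σ_e = wf_p · μ_e ,

so the prior both shifts with the sequence onset (primacy/assimilation) and
scales its uncertainty with its own mean (scalar variability). Each interval
is measured with Weber noise inflated by a per-sequence-type volatility
factor,

    σ_i² = k_j · (wf_s · D_i)² ,     j ∈ {AS, DS, RS},

and the reproduced interval is the Bayesian (precision-weighted) fusion of
prior and measurement,

    R_i  = (1 − w)·μ_e + w·D_i,      w = σ_e² / (σ_e² + σ_i²),
    σ_r² = σ_i²·σ_e² / (σ_i² + σ_e²).

The fusion weight normalization w = σ_e²/(σ_e²+σ_i²) is the unique choice
consistent with the posterior-variance formula above (standard conjugate
Gaussian fusion); w ∝ 1/σ_i² alone does not pin it down. The 700 ms anchor
is the true design mean and is deliberately not estimated. μ_e and σ_e are
recomputed per trial from that trial's D₁, so prior uncertainty co-varies
with the first interval.

Consequences used throughout the tests: regressing noiseless R on D gives a
slope strictly below 1 for any finite wf_p (central tendency), the slope
decreases in k_j (volatile sequences regress harder), the predicted sequence
mean increases in D₁ through μ_e (AS > RS > DS ordering), and
σ_r ≤ min(σ_i, σ_e).

## Parameters

| symbol | meaning                                   | support | reference value |
|--------|-------------------------------------------|---------|-----------------|
| wf_s   | sensory Weber fraction                    | > 0     | 0.18            |
| wf_p   | prior Weber fraction                      | > 0     | 0.35            |
| α      | first-interval weight in the prior mean   | [0, 1]  | 0.195           |
| k_AS   | volatility factor, accelerating sequences | > 0     | 2.0             |
| k_DS   | volatility factor, decelerating sequences | > 0     | 2.4             |
| k_RS   | volatility factor, random sequences       | > 0     | 2.13            |

The reference column is the group-level estimate for this paradigm, used as
the simulator's default truth; all are configurable.

## Synthetic data

`simulate.simulate_dataset` emulates the study conditions: 15 participants,
each a randomized session of 264 trials (88 per sequence type, 44 per
interval set within type, six blocks of 44), reproduced intervals drawn
independently per position from Normal(R_i, σ_r_i) truncated to positive
values by resampling (clipping would put a point mass at zero). Noise enters
once, at the reproduction stage, with the model's posterior SD: the model
does not specify a sensory/motor decomposition of trial-level noise, so the
minimal one-stage scheme consistent with σ_r² is used. Optional
between-participant heterogeneity comes from independent truncated-normal
population draws.

What the generator deliberately does not emulate: feedback-driven learning,
cross-trial sequential dependencies, and any recency mechanism — k_j is a
single constant per sequence type, so the last interval of a random sequence
influences predictions only compositionally (trials ending long tend to
start shorter, lowering μ_e). Real data show a much larger last-interval
effect on the slope and excess RS reproduction variability (motor execution
of irregular patterns), neither of which this generative model produces.
Passing tests on synthetic data therefore validate the pipeline's
correctness under the model's assumptions, not those extra-model phenomena.

## Analysis choices

- **Outlier rule.** Per participant × condition cell, on per-trial means of
  the four reproduced intervals: a trial is excluded when its mean deviates
  from the cell mean by at least twice the cell's population SD (single
  pass; zero-SD cells excluded nothing). On simulated data at the reference
  truth this removes ~4% of trials. Iterative re-trimming is intentionally
  avoided.
- **Slopes.** Plain OLS of reproduced on sample interval pooled over
  positions, per participant × condition (optionally × interval set, then
  averaged); no errors-in-variables correction. Groups need ≥ 2 distinct
  sample values.
- **Endpoint analysis.** Random-sequence trials are tagged short/middle/long
  by the first or last interval relative to 700 ms (only set 2 contains a
  700 ms interval, hence "middle"); the same means/slopes are computed per
  tag.
- **RM ANOVA.** The classical one-way repeated-measures F with
  (k−1, (k−1)(n−1)) df is provided as a descriptive utility (cross-checked
  against pingouin in the tests); no post-hoc machinery.
- **Condition means** average rows within participant × condition, then
  across participants.

## Fitting

Each reproduced interval contributes a Normal log-density with mean R_i and
SD σ_r_i; trials are independent, so the fit is invariant to trial order.
The two-stage protocol first estimates {wf_s, wf_p, α, k_AS, k_DS} per
participant on the structured (AS + DS) trials, then freezes those at their
stage-1 point estimates and estimates k_RS alone on the RS trials (point
freezing, not full posterior propagation). Fits are per-participant and
independent; group values are means across participants. No hierarchical
pooling.

Priors are weakly informative and support-respecting: wf_s, wf_p ~
half-normal(0.5), α ~ uniform(0, 1), k_j ~ half-normal(3). The default
estimator is multi-start MAP (L-BFGS-B on the log posterior, three seeded
starts, bounds wf ∈ (10⁻⁴, 3), α ∈ [0, 1], k ∈ (10⁻³, 30)); approximate SDs
come from the optimizer's inverse-Hessian estimate. An ensemble-MCMC
estimator (emcee; walkers initialized at the MAP; posterior mean ± SD;
split-R-hat via arviz, flagged above 1.05) is available where full
posterior summaries are wanted.

### Identifiability

The likelihood depends on wf_s and the volatility factors only through the
products c_j = k_j·wf_s² (σ_i² = k_j·wf_s²·D_i², and nothing else contains
wf_s). With a free k_j in every fitted condition there is an exact ridge:
any (wf_s, k_j) with fixed c_j fits identically, and the split is decided by
the priors. Under the defaults the ridge maximum sits near
wf_s = (Σ_j c_j²/9)^(1/6), which for c_AS, c_DS at the reference truth gives
wf_s ≈ 0.29 and k_j ≈ 0.8–0.9 regardless of how the truth splits them.
Recovery studies should therefore compare α, wf_p, and either the products
c_j or the effective per-condition Weber fractions √k_j·wf_s — all of which
recover well at the 15 × 264 scale — rather than wf_s and k_j individually.
Stage 2 inherits the stage-1 wf_s, so k_RS is recovered up to the same
ridge (c_RS = k_RS·wf_s² is identified). Fixing k in one condition to 1, or
an informative prior on wf_s, would break the ridge; both change the model
and are left to the user.

### Goodness of fit

R² is the squared Pearson correlation between model-predicted and observed
mean reproductions over the per-sample-interval means (7 distinct intervals
when pooling both sets) within participant × condition, averaged across
participants per condition. On simulated data at the reference truth it is
≈ 0.98 in every condition.

## Numerical and scale choices

All durations are float64 milliseconds internally; seconds appear only at
I/O edges (auto-detected by magnitude). Randomness flows from one master
seed through `numpy.random.SeedSequence` spawns (session, noise and
population streams per participant), so datasets are bit-reproducible.
Random-order sequences are drawn by indexing the enumerated list of 22
admissible permutations, giving exact uniformity. Degenerate inputs
(D_i ≤ 0, zero variances) are rejected rather than special-cased, since
Weber scaling is undefined at zero. Simulation-based checks use 100
replicate datasets for qualitative signatures and 20 replicates for
recovery, at the full 15 × 264 study scale (a few minutes end to end);
single-dataset demonstrations use one 15 × 264 dataset.

## Known limitations

- No motor-noise component and no recency mechanism: RS reproduction
  variability and last-interval slope effects in real data exceed what the
  model generates.
- The wf_s / k_j ridge above: per-parameter point estimates of those
  quantities are prior-dependent by construction.
- The 700 ms prior anchor is assumed veridical; systematic overestimation of
  auditory intervals would shift predicted means.
- Per-participant independent fits ignore population structure; a
  hierarchical extension is out of scope.
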