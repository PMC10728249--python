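# patterntiming

Tools for studying how the **temporal order of a short auditory sequence**
shapes its reproduction. In the paradigm this package implements, listeners
hear five beeps demarcating four intervals (2.8 s in total) and tap the
pattern back. Two four-interval sets — [400, 500, 900, 1000] ms and
[400, 600, 700, 1100] ms — share the same mean (700 ms) and SD (294.39 ms)
but are presented in different orders: ascending (a *decelerating* rhythm,
DS), descending (*accelerating*, AS), or a random non-monotone order (RS).
Reproduction shows a *central-tendency bias* — long intervals are reproduced
too short and short ones too long — whose strength depends on the sequence
structure, and a mean reproduction assimilated toward the first interval.

The package provides, as plain Python functions plus a thin CLI:

- **design** — canonical interval sets, sequence construction (uniform over
  the 22 admissible random orders), randomized 264-trial sessions, and the
  ±15% / ±50% feedback bands;
- **observer** — the closed-form generative Bayesian observer. The ensemble
  prior mean is a weighted average of the first interval and the design mean,
  μ_e = α·D₁ + 700·(1−α), with σ_e = wf_p·μ_e; each interval is measured with
  volatility-scaled Weber noise, σ_i² = k_j·(wf_s·D_i)²; reproduction is the
  precision-weighted fusion R_i = (1−w)·μ_e + w·D_i with
  w = σ_e²/(σ_e²+σ_i²) and σ_r² = σ_i²σ_e²/(σ_i²+σ_e²);
- **simulate** — trial-level synthetic datasets drawn from that observer
  (Normal(R_i, σ_r_i), truncated positive), at the study scale of
  15 participants × 264 trials by default;
- **analysis** — the 2·SD outlier rule on per-trial sequence means,
  central-tendency slopes (OLS of reproduced on sample interval), condition
  means and reproduction variability, first/last-interval categorization of
  random sequences, and a one-way repeated-measures ANOVA utility;
- **fitting** — the two-stage estimation protocol: fit wf_s, wf_p, α, k_AS,
  k_DS per participant on the structured sequences, then freeze the shared
  parameters and fit k_RS on the random sequences; seeded MAP by default,
  ensemble MCMC (emcee) optional; R² between predicted and observed
  per-interval means.

## Worked example

```sh
patterntiming simulate --seed 11 --out demo
patterntiming analyze  --input demo/trials.csv --out demo_an
patterntiming fit      --input demo/trials.csv --seed 11 --out demo_fit
```

`analyze` prints the group-mean central-tendency slopes and writes
`slopes.csv`, `condition_means.csv`, `endpoint_analysis.csv` and
`report.json`:

```json
{
  "trials_total": 3960,
  "trials_excluded": 167,
  "exclusion_fraction": 0.042,
  "mean_slope_by_condition":      {"AS": 0.711, "DS": 0.531, "RS": 0.600},
  "mean_reproduced_by_condition": {"AS": 685.9, "DS": 633.1, "RS": 655.6}
}
```

Read: about 4% of trials are discarded by the 2·SD rule; all slopes are
below 1 (central tendency), accelerating sequences show the weakest bias
(slope 0.71) and the highest mean reproduction (686 ms), because they start
with a long interval that pulls the ensemble prior upward, while
decelerating sequences show the strongest pull toward the mean. `fit` prints
the per-condition R² between model-predicted and observed per-interval mean
reproductions — `{"AS": 0.98, "DS": 0.98, "RS": 0.98}` here — and writes
`fits.csv` (per-participant estimates) and `predictions.csv`.

A parameter-recovery study over replicate simulated datasets is one command:
`patterntiming recover --replicates 5 --seed 7`. Note that the likelihood
constrains k_j and wf_s only through the product k_j·wf_s² (see
`docs/methods.md`), so the recovered split between them reflects the priors;
α, wf_p and the per-condition effective Weber fraction √k_j·wf_s are the
data-identified quantities.

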