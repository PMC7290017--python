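# ensemblepull

Statistical pipeline for **unintentional ensemble averaging of emotional
valence**: when an observer who has already rated individual scenes
(-5 … +5, no 0) re-rates a cued scene presented among three task-irrelevant
scenes of the same valence sign, is the new rating pulled toward the mean
rating of the surrounding set?

The package is written for visual-psychophysics researchers who run (or
simulate) two-part rating designs and want the full analysis chain as
tested, reusable code:

* **Bias analysis** — per-trial inclusion (`|m − r1| > 0.5`; restricted
  variant keeps only targets rated exactly ±3), toward/away/none shift
  classification, per-observer toward-proportions
  (`proportion = #toward / #included`, unchanged ratings in the
  denominator).
* **Chance levels** — Monte-Carlo simulation of random responders on the
  real trial skeletons, its exact enumeration, the closed-form restricted
  level (`(2/10 + 7/10)/2 = 0.45` for balanced designs), and the matched
  no-pull chance level for model-generated data.
* **Single-item sampling null** — replaces the ensemble mean with one
  randomly sampled distractor per trial (default 5000 iterations) to show
  the pull reflects the aggregate, not any single item.
* **Pull magnitude** — mean observed shift as a percentage of the mean
  available ensemble-target difference (100% = reporting the ensemble
  mean instead of the target), plus a moment estimator of the pull weight.
* **Inference** — one-sample and pooled two-sample t tests, Pearson r,
  and the JZS (Cauchy-prior, scale 0.707) Bayesian independent-samples
  t test by numerical integration.
* **Synthetic observers** — a generative model
  `response = snap(r1 + w·(m − r1) + ε)`, `ε ~ N(0, σ)`, with seeded,
  bit-reproducible observer streams, so every stage is exercisable with no
  external data; plus toy images and the 8×8 tile scrambler with exact
  pixel-multiset conservation.

See `docs/methods.md` for the model, its assumptions, and what synthetic
results do and do not show about human data.

## Worked example

Simulate a 50-observer × 190-image × 200-trial experiment with pull weight
0.16 and response noise 0.75, analyze it, and render the report:

```sh
ensemblepull full-run --seed 1 --out demo
```

The restricted-analysis section of the printed report:

```
## Condition: upright — restricted analysis

- observers analyzed: 50
- mean bias proportion: 0.335 (SD 0.106)
- chance level, uniform random responder: 0.438 (exact 0.439)
- chance level, matched no-pull responder: 0.252
- t vs uniform chance: t(49) = -6.91, p = 9.21e-09
- t vs no-pull chance: t(49) = 5.53, p = 1.25e-06
- pull magnitude: shift 1.112 of available 1.011 -> 110.0% of maximum
- recovered pull weight: 0.173
- memory consistency (mean |r2 - r1|): 0.536
```

Reading this: the generated observers shift toward the irrelevant ensemble
on 33.5% of included restricted trials — significantly **above** the 25.2%
chance level of a matched no-pull responder (t(49) = 5.53), which is the
correct null for this response model, while sitting below the 45%-type
uniform-random-responder level (0.438 on these skeletons) because the
snap-Gaussian model repeats the Part I rating on about half of the trials.
The moment estimator recovers the generating pull weight (0.173 ≈ 0.16);
the toward-conditioned magnitude (110% of maximum) illustrates the
selection bias discussed in the methods note. Each run directory also
contains `ratings.csv`, `trials.csv`, per-observer `bias_<mode>.csv`,
`summary.csv`, `report.md`, a seed-complete `manifest.json`, and
`run.log`.

The same stages are available as `simulate`, `analyze`, `chance`, and
`report` subcommands, and as plain library calls
(`ensemblepull.generate_observers`, `observer_bias`, `monte_carlo_chance`,
`single_item_null`, `jzs_bayes_factor`, …).

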