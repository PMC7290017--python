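# Methods

## The experimental design being modeled

`ensemblepull` analyzes two-part valence-rating experiments. In Part I an
observer rates every image in a stimulus pool on a bipolar integer scale
from -5 (very negative) to +5 (very positive) with 0 excluded. In Part II
the observer views four-image sets whose members all share the sign of
their Part I rating (valence-homogeneous sets); one image is cued, and the
observer re-rates only that image. The scientific question is whether the
second rating of the cued image is pulled toward the mean Part I valence
of the three task-irrelevant distractors (the "irrelevant ensemble") —
unintentional ensemble averaging.

## The bias statistic

For each trial let `r1` be the target's Part I rating, `r2` its Part II
rating, and `m` the mean Part I rating of the three distractors.

* **Inclusion.** A trial enters the analysis only if `|m - r1| > 0.5`
  (strict), so that a one-step shift toward the ensemble is meaningful.
  The **restricted** analysis additionally requires `|r1| = 3`, the
  midpoint of each half-scale; this removes the response-range artifact by
  which extreme Part I ratings can only move inward, which inflates the
  full-analysis chance level.
* **Direction.** A trial is *toward* if `sign(r2 - r1) = sign(m - r1)` and
  `r2 != r1`; *away* if the signs oppose; *none* if unchanged. Unchanged
  ratings count in the denominator but not the numerator — this convention
  is what makes the restricted chance level under uniform random
  responding exactly 45% (below).
* **Aggregation.** The per-observer bias proportion is
  `#toward / #included`; group inference is per-observer proportion first,
  then a one-sample t across observers (df = n_observers - 1). Observers
  with zero included trials are flagged and excluded from the group test.

## Chance levels

Two distinct no-bias references are computed, and they answer different
questions:

1. **Uniform random responder** (`monte_carlo_chance`, `exact_chance`,
   `analytic_chance_restricted`). Simulated observers keep the real trial
   skeletons `(r1, m)` but answer uniformly at random over the 10 legal
   scale values. In the restricted analysis with the target at +3, a
   uniform response is toward an ensemble above the target for 2 of the 10
   values (+4, +5) and toward one below for 7 of 10 (everything under +3
   except +3 itself); with above/below balanced the level is
   `(2/10 + 7/10)/2 = 0.45` exactly. The Monte-Carlo estimator converges
   to this closed form and is used as the reference for human-style data.
   The full-analysis chance level depends on the empirical skeleton
   distribution (it is ~0.58 under a uniform rating marginal) and is
   reported per run rather than as a constant.
2. **Matched no-pull responder** (`pull_model_chance`). For data generated
   by the package's own response model (below), the correct null is the
   same model with the pull switched off (`w = 0`), not a uniform
   responder: a `w = 0` responder mostly repeats its Part I rating, so its
   toward-proportion is far below 45%. With the target at ±3 every
   crossing of the first rounding boundary on the ensemble's side is a
   toward response, so the restricted level is exactly
   `Phi(-0.5 / sigma)` (0.2525 at the default sigma = 0.75). For arbitrary
   skeletons the level is assembled from snap-bin Gaussian probabilities.
   Type-I-error calibration of the group t test is run against this
   matched level; against the 45% uniform-responder level a `w = 0`
   generator is (correctly) rejected as *below* chance, which is a
   statement about response concentration, not about ensemble pull.

## The generative model

`synthetic.generate_observers` draws Part I ratings i.i.d. from a
`rating_marginal` (default uniform over the 10 legal values — chosen
because the restricted analysis of the original design retained roughly
10% of trials, consistent with ~10% mass per scale point), builds
valence-homogeneous trials (side by fair coin where feasible, 4 distinct
images sampled without replacement, target cued uniformly), and fills
Part II responses by a linear pull model:

    response = snap(r1 + w * (m - r1) + eps),   eps ~ Normal(0, sigma)

Defaults: 50 observers x 190 images x 200 trials, `w = 0.16`,
`sigma = 0.75`. The `snap` rule rounds half away from zero, maps a raw 0
to the nearer of -1/+1 (ties to +1), and clamps to [-5, +5]; it is stated
explicitly because the discretization, not the linear core, determines the
model's small-shift behavior. One root seed fans out to per-observer,
per-stage `SeedSequence` streams, so runs are bit-reproducible and
observers independent.

### What the generator does and does not emulate

It reproduces the design's trial structure and a parametric pull toward
the distractor mean, which is what the analysis pipeline needs to be
exercised end to end. It does **not** reproduce human response behavior:
real observers re-rate with large, non-Gaussian dispersion (they changed
their rating on most included trials), whereas the snap-Gaussian model at
`sigma = 0.75` repeats the Part I rating on about half of them. Two
consequences, both intrinsic to the model rather than defects of the
analysis:

* The synthetic toward-proportion (~0.33 restricted at the defaults) lies
  *between* the matched no-pull chance (0.2525) and the uniform-responder
  chance (0.45). A pull of `w = 0.16` moves the raw response by at most
  `0.16 * 2 = 0.32` on restricted trials — never past the 0.5 rounding
  boundary on its own — so the pull is only visible where noise carries
  the response near a boundary. Passing tests on synthetic data therefore
  demonstrate detection of the generated pull against its matched null,
  not a reproduction of human effect sizes.
* The pull-magnitude statistic conditioned on toward-trials is strongly
  selection-biased upward under this generator (every toward shift is at
  least one whole scale step, while available differences on restricted
  trials are near 1), so `pct_of_max` from synthetic toward-trials is not
  comparable to `w`. The unbiased recovery statistic is
  `estimate_pull_weight`: mean signed-toward shift over *all included*
  trials divided by the mean available difference, which recovers the
  generating `w` to within ±0.05 at the default design (the restricted
  variant is preferred; the full variant carries a small (+0.03) upward
  clamp asymmetry from targets at ±4/±5). `pull_magnitude` also accepts
  `trials="included"`, whose arithmetic matches how printed magnitude
  components of the form "mean shift 0.1 against mean available
  difference 0.61, i.e. ~16% of maximum" must have been pooled, since a
  toward-only mean shift below one scale step is impossible with integer
  ratings.

### Fast restricted path

`simulate_restricted_proportions` draws restricted trial skeletons
directly — target at ±3, ensemble mean the average of three same-sign
uniform ratings conditioned on passing inclusion (a closed-form
conditional pmf over sums 3..7 and 11..15 of three 1..5 draws) — and
vectorizes the response model over (experiments x observers x trials).
It is distributionally equivalent to running the object-level generator
plus restricted analysis for the statistics it feeds (per-observer
toward-proportions) and makes thousand-replicate calibration studies take
seconds; an agreement test against the object-level path guards the
equivalence.

## Single-item sampling null

To show the pull reflects the aggregate rather than one item, each
trial's reference value is replaced by the Part I rating of one uniformly
sampled distractor; inclusion (`|single - r1| > 0.5`) and direction are
recomputed against that single rating, and per-iteration proportions are
averaged (default 5000 iterations). Whether the original analysis
re-applied the inclusion rule to the sampled item or froze the
ensemble-based trial set is not documented; re-application is the default
here (the analysis is described as the bias analysis with a single item
in the ensemble's place), and `reuse_ensemble_inclusion=True` implements
the frozen variant. Iterations in which no trial passes inclusion are
dropped from the average; an observer with no included trial in any
iteration is flagged. On ensemble-pull data the single-item proportion
falls below the full-ensemble proportion (the qualitative ordering the
design predicts); the package tests the ordering, not particular values.

## Inference

t statistics, Pearson r, and their two-sided p-values are computed from
the textbook formulas (p via scipy's t distribution) so that scipy,
statsmodels, and pingouin remain independent oracles in the tests. The
two-sample t is the pooled-variance form (the df it implies is what
published df values of the kind n1 + n2 - 2 require). The Bayesian
independent-samples t test is the Jeffreys–Zellner–Siow default: a
Cauchy(0, 0.707) prior on the standardized effect size, evaluated by
adaptive quadrature of the g-integral (Cauchy as a scale mixture of
normals), with `BF01 = 1/BF10`; the tests cross-check it against a
noncentral-t-route Gauss–Legendre quadrature (tolerance 1e-4) and against
pingouin. Two-sided p-values are used throughout; no multiple-comparison
correction is applied.

## Scrambling

`scramble_image` cuts a gray-level image into an 8x8 grid of tiles
(dimensions must divide evenly) and rearranges them by a uniformly random
permutation, conserving the pixel multiset exactly. Uniformity over
permutations is chi-square tested on a 2x2 grid (24 orders). The rated
consequences of scrambling are emulated at the data level by
`simulate_scrambled_ratings` (`scrambled = a * original + noise`); the
closed form `r = a*sigma_x / sqrt(a^2 sigma_x^2 + sigma_eps^2)` inverts
to the noise level for any target original–scrambled correlation.

## Numerical conventions and limitations

* Inclusion threshold strictly greater than 0.5; with integer ratings and
  thirds-valued ensemble means the boundary `|m - r1| = 0.5` is not
  constructible from data, but skeleton inputs on the boundary are
  excluded.
* Proportion denominators always count "none" trials; zero included
  trials raise an explicit undefined-summary error rather than returning
  NaN.
* All stochastic stages take explicit seeds; run manifests record them.
* Problem sizes in the test suite (e.g. 1000 replicate experiments of
  50 x 20 restricted trials for calibration, 10,000 simulated responders
  for chance levels) were chosen so the full suite completes in a few
  seconds while keeping Monte-Carlo error an order of magnitude below the
  tolerances asserted.
* Inversion of ensemble images is a presentation-level manipulation: it
  changes nothing about the rating tables this pipeline consumes, so the
  inverted condition is carried as a label only. Real scrambled-image
  pixel analysis, response times, and cue positions are out of scope.
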