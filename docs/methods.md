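# Methods

## Problem setting

`memdecode` implements single-trial decoding of visual memory categories
(Animal, Building, Plant, Tool, Vehicle) from ensembles of hippocampal
CA3/CA1 single units recorded in a delayed match-to-sample (DMS) task.
The input of the decoder is the spatio-temporal spike pattern `x` of all
simultaneously recorded neurons in a 2-second window around a behavioral
event (sample response for memory encoding, match response for
retrieval), binned at 10 ms; the output is a binary one-vs-rest category
label `y`.  The interesting regime is short data (order 150 trials)
against a very high-dimensional input (tens of neurons x 200 bins),
which rules out classical peri-event-histogram approaches and motivates
a heavily regularized ensemble model whose fitted representation is
itself the scientific readout.

## The ensemble multi-temporal-resolution classifier

The model is a two-layer stack, `y = g(f_r^(m)(x))`:

* **Base learners** `f_r^(m)`.  For each temporal resolution, the binned
  spike pattern of every neuron is projected onto a B-spline basis with
  `m` uniform interior knots over the window of length `M`; the
  resolution of that basis is `M/(m+1)`.  On these features an
  L1-regularized logistic regression is fit.  Each base learner sees a
  single resolution and is a weak classifier by itself.
* **Bagging.**  Per resolution, `R` replicas are trained on bootstrap
  resamples of the training trials (a disjoint-partition mode is
  available via `bag_mode="partition"`).  Bagging reduces estimation
  variance and, as importantly for interpretation, the union of the
  replicas' L1 supports covers the informative (neuron, time) cells far
  better than any single sparse fit.
* **Meta-learner** `g`.  A second L1-logistic model stacks the base
  learners' predicted probabilities.  Its sparsity performs data-driven
  resolution selection: base learners with zero meta weight drop out of
  the decision function entirely.

Stacking is leakage-safe: the meta-learner is trained on out-of-fold
base predictions (the bank is refit inside each inner fold and predicts
only trials it has not seen).  All hyperparameters are chosen on inner
folds; all reported performance comes from outer-fold test trials that
influenced neither coefficients nor hyperparameters (nested
cross-validation, default 5 outer x 4 inner stratified folds).

Decoding performance is summarized by the Matthews correlation
coefficient computed from the held-out confusion matrix, with the
convention that a zero marginal factor (degenerate predictor or labels)
yields MCC = 0.

### Numerical choices

* The L1 penalty `lambda` multiplies the mean negative log-likelihood;
  features are z-scored with training-fold statistics before fitting
  (the penalty is scale-sensitive, and the B-spline feature scales vary
  systematically with resolution) and coefficients are mapped back to
  the raw feature scale afterwards, so prediction is a plain dot product
  and coefficients compose into the functional matrix below.
* Weights are fit with scikit-learn's liblinear solver; the intercept is
  then re-optimized exactly by a one-dimensional Newton step, because
  the model's intercept is not penalized.  This preserves the analytic
  L1 limit: as `lambda -> inf` every weight is zero and the intercept
  equals the logit of the class prevalence.
* `lambda` is searched on a descending log grid (default 30 points,
  `1e-4..1`) warm-starting along the path within each inner fold.  The
  default selection rule is the **one-standard-error rule**: the largest
  penalty whose mean validation cross-entropy is within one standard
  error of the minimum.  Near-separable synthetic data make the plain
  loss minimizer insensitive to spurious features (extra noise columns
  barely hurt validation loss), which inflates the fitted support;
  the 1-SE rule is the standard remedy and markedly improves the
  recovery of the true zero regions.  `lambda_rule="min"` restores the
  plain minimizer.  Exact ties always resolve to the larger penalty.
* Degenerate bootstrap bags (single class) are redrawn up to 20 times
  before a `DegenerateFoldError` is raised; a category whose label
  column is constant is skipped with a warning and reported as
  undefined.
* One master seed fans out to all randomness (fold shuffles, bags,
  permutations) through `numpy.random.SeedSequence` spawning, making the
  whole pipeline bit-reproducible; liblinear itself is deterministic.

### Basis order

`build_basis` supports any spline order; the library default is cubic
(order 4), the conventional smooth choice for functional-data analysis.
For interpretation-focused analyses the desk-scale configurations in the
tests and the acceptance script use order 1 (piecewise-constant,
disjoint supports).  The reason is the zero-region semantics of the
functional matrix: a basis function's entire support is marked non-zero
as soon as its coefficient survives the L1 penalty, so the spatial
granularity of the interpretable map equals the basis support
(`order x M/(m+1)`).  With cubic splines even a perfectly recovered
coefficient smears over four knot spans and systematically biases the
temporal-sparseness estimate downward; with order-1 boxes the marked
region tracks the true active interval up to one resolution width.

## The sparse classification functional matrix (SCFM)

A trained per-category stack is rendered as the neurons x time map

    F'(n, tau) = sigmoid( w0' + sum_m sum_j b_j^m(tau) w(n, j) w'(m) )

where `w` are base-learner coefficients, `w'` meta weights and `w0'` the
meta intercept.  `sigmoid(w0')` is the baseline of the map; cells where
every product vanishes sit exactly at the baseline and are inert: a
spike there cannot move the decoded probability.  Cells above the
baseline are locations where spikes raise the decoded category's
probability, cells below lower it.  Because a sigmoid is never
literally negative, the positive/negative/zero trichotomy is defined
relative to the baseline on the linear (pre-sigmoid) scale with a
tolerance `zero_tol` (default 1e-6).

The formula indexes base learners by `m` while `w(n, j)` carries no
replica index; the implemented reading averages coefficients over the
bagging replicas within each resolution and weights by the summed meta
weight of that resolution (the per-replica sum is available with
`mode="per_replica"`; both coincide for a single replica).

Downstream statistics:

* **Masked scores** — the inner product of a trial's spikes with the
  baseline-centered map, `sum spikes * (F' - baseline)`.  Centering
  makes zero regions exactly inert.  On data with embedded signal the
  masked score of decoded-category trials exceeds that of the other
  categories.
* **Spatial sparseness** — fraction of neurons whose entire row is
  within `zero_tol` of baseline (no contribution to that category).
* **Temporal sparseness** — per neuron, the fraction of the window at
  baseline; summarized as mean ± SD both over all neurons and over
  contributing (non-flat) neurons only, since the all-neuron average
  mixes in the trivially-flat non-contributing rows.

## Permutation feature importance and the CA3/CA1 decomposition

The model's dependence on a feature group (all features of one temporal
resolution, of one region, or of one neuron) is the increase in held-out
loss when the group's columns are jointly permuted across the held-out
trials of each outer fold — one shared trial permutation per repeat, so
within-group dependence is preserved.  Loss is the mean binary
cross-entropy divided by the entropy of the held-out label marginal
("normalized cross-entropy"; the unnormalized mean is available).
Contributions are averaged over `n_permutations` repeats (default 50),
clipped at zero for reporting (raw values are retained) and normalized
to sum to one across groups.

The regional decomposition runs three passes — CA3 alone, CA1 alone,
both together — and splits the joint contribution as

    R          = C_CA3 + C_CA1 - C_both        (redundancy)
    unique_CA3 = C_CA3 - R
    unique_CA1 = C_CA1 - R

so `unique_CA3 + unique_CA1 + R = C_both` holds as an algebraic identity
(raw, unclipped contributions enter the algebra).  Per-neuron
contributions divide each region's total by its neuron count to balance
the 6:4 CA3:CA1 electrode layout.

## The synthetic DMS generator

Human hippocampal DMS recordings are not publicly available, so the
generator emulates sessions of that kind:

| parameter | default | rationale |
| --- | --- | --- |
| neurons | 20 (12 CA3 / 8 CA1) | a typical per-subject micro-electrode yield (tens of units; 6:4 CA3:CA1 probe layout) at desk cost |
| trials | 150, balanced over 5 categories | a typical 1–2 session DMS yield (100–150 trials per session) |
| window | (-1 s, +1 s) around the sample response | a 2 s decoding window; symmetric alignment covers pre- and post-response activity |
| bins | 10 ms | fine enough that the finest base learners are not aliased |
| baseline rate | 5 Hz | typical hippocampal pyramidal-cell range |
| coding neurons | 75% | the distributed-coding regime in which 70–80% of neurons participate in encoding |
| temporal sparseness target | 0.75 | the temporal-coding regime in which 20–30% of the window carries signal |
| modulation depth | 1.25 | held-out MCC well above the null while the task stays non-trivial, as in real categorical decoding where accuracies are moderate |

Each coding neuron has **one** contiguous active interval, bin-aligned
with a uniformly random onset and length `(1 - target) * M`, shared by
all five categories; categories differ by a modulation gain inside it,
assigned per neuron as a random permutation of the profile
`(-1, -1, -1, 2, 2)` (per-bin probability
`clip(p0 * (1 + gain * depth), 0, 1)`).  Two design points matter:

* *Shared interval.*  If every (neuron, category) pair had its own
  interval, the one-vs-rest contrast of a category would be non-zero
  over the union of all five categories' intervals (~75% of the window)
  and the generating temporal sparseness would be unrecoverable from any
  decoder's map — the target would not describe the data.  With a shared
  interval the contrast is confined to it, so the generating fractions
  are the recoverable truth.
* *Two-cluster gain profile.*  With gains drawn from a continuum, the
  category nearest the neuron's mean response has a one-vs-rest contrast
  arbitrarily close to zero — an unlearnable sign.  The two-cluster
  profile bounds every category's contrast away from zero (the weakest
  cell is ~3.5x the baseline probability) while making single neurons
  individually ambiguous between same-gain categories, i.e. a genuine
  population code.

Spikes are Bernoulli per bin (an inhomogeneous Poisson process thinned
to the bin grid) — exactly the form the decoder consumes.  Trials are
assigned round-robin to categories and shuffled.  The ground-truth
contrast map `intensity(c) - mean(intensity(others))` per neuron-bin is
the oracle for sign-map recovery.

A full synthetic session also draws flat-baseline spikes over a span
preceding the sample presentation, so the time-shifted control (a window
that ends at or before that event and therefore cannot contain category
information) can be extracted from the same event store.

### What the generator does not emulate

Real recordings have bursting and refractory structure, theta-locked
rate fluctuations, cross-neuron noise correlations, non-stationarity
across the session, spike-sorting errors and partially-observed
ensembles.  Passing the recovery tests therefore shows that the pipeline
is correct and well-calibrated under its own assumptions — independent
Bernoulli spiking with localized, stationary category modulation — not
that real hippocampal data meet those assumptions.

## Desk-scale configurations

The shipped tests and the acceptance script run the full pipeline at a
reduced, fixed scale chosen so the whole suite completes on one CPU in
minutes: 20 neurons, 150 trials, a four-rung ladder `m = (7, 15, 31,
63)` of order-1 bases (resolutions 250 ms down to ~31 ms), 10–20 bagging
replicas, an 8-point penalty grid and 5x3 nested cross-validation.  The
library defaults (six-rung ladder to m = 63, cubic bases, 10 replicas,
30-point grid, 5x4 folds) are what an analysis of real recordings would
start from.

## Known limitations

* The SCFM composes base coefficients with meta weights *linearly*,
  while the meta-learner actually consumes sigmoid-transformed base
  outputs; the map is an interpretable first-order summary, not the
  exact decision function.
* Sign-map recovery is bounded by the redundancy of the ensemble: an L1
  model does not need every informative neuron, and only the union of
  bagged supports approaches full coverage.  Cells whose true contrast
  is small relative to noise are systematically reported as zero.
* Per-subject models only; no cross-subject pooling or SCFM
  registration.
* Only MCC and cross-entropy are implemented as scores, matching the
  analysis the pipeline reproduces.
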