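# memdecode

Decoding visual memory categories from hippocampal spike patterns with
an ensemble multi-temporal-resolution classifier.

## The problem

During a delayed match-to-sample (DMS) task, human hippocampal CA3 and
CA1 neurons emit spatio-temporal spike patterns around the behavioral
events that mark memory encoding (sample response) and retrieval (match
response).  Whether those patterns carry the *category* of the
remembered image (Animal, Building, Plant, Tool, Vehicle) — and at what
temporal resolution, how sparsely, and with what division of labor
between CA3 and CA1 — is a question about the neural code that cannot
be answered by averaging peri-event histograms over trials: at ~150
trials per subject and tens of neurons x hundreds of time bins per
trial, the input is far higher-dimensional than the data.

`memdecode` implements the analysis pipeline for this regime, for
computational neuroscientists working with event-aligned single-unit
recordings (or anyone who wants a tested reference implementation of
the method):

1. **Featurization** — binned spikes are projected onto B-spline bases
   with `m` interior knots over the decoding window of length `M`; each
   basis is one temporal resolution `M/(m+1)`.
2. **Decoder** — the stacked ensemble `y = g(f_r^(m)(x))`: per
   resolution, bagged L1-regularized logistic base learners
   `f_r^(m)`; an L1-logistic meta-learner `g` fuses their predicted
   probabilities and thereby selects temporal resolutions.  Everything
   runs under nested cross-validation (hyperparameters on inner folds,
   performance on held-out outer folds), scored with the Matthews
   correlation coefficient

       MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

   with MCC = 0 when a marginal factor vanishes (degenerate predictor).
3. **Interpretation** — the trained stack is rendered as a sparse
   classification functional matrix (SCFM) over neurons x time,
   `F'(n,τ) = σ(w0' + Σ_m Σ_j b_j^m(τ) w(n,j) w'(m))`; regions above /
   below the baseline `σ(w0')` mark where spikes raise / lower the
   decoded category's probability, and zero regions are inert.  From it:
   masked trial scores, spatial sparseness (fraction of non-contributing
   neurons) and temporal sparseness (non-contributing fraction of the
   window per neuron).
4. **Importance** — grouped permutation feature importance on held-out
   trials: per-resolution contributions to the normalized cross-entropy
   loss, and the CA3/CA1 decomposition into unique contributions and
   redundancy `R = C_CA3 + C_CA1 − C_both`.
5. **Controls** — a time-shifted window that precedes the sample
   presentation, and label shuffling across trials; both must decode at
   chance.
6. **Synthetic data** — a DMS-like generator with known ground truth
   (coding neurons, active intervals, per-category modulation gains), so
   every stage above is testable without any recording.

See `docs/methods.md` for the model, its assumptions, parameter
defaults, and what the synthetic benchmarks do and do not demonstrate.

## Worked example

```python
from memdecode import (SimConfig, DecoderConfig, sample_intensities,
                       simulate_trials, fit_ensemble, evaluate_nested,
                       compute_scfm, spatial_sparseness, temporal_sparseness)

sim = SimConfig(seed=7)                      # 20 neurons, 150 trials, 2 s window
intensities = sample_intensities(sim)
tensor, labels = simulate_trials(intensities, sim)

cfg = DecoderConfig(knot_ladder=(7, 15, 31, 63), order=1, n_replicas=10,
                    n_lambda=8, lambda_min=1e-3, inner_folds=3,
                    tol=1e-6, max_iter=2000, seed=0)
decoder = fit_ensemble(tensor, labels, cfg)
result = evaluate_nested(decoder, tensor, labels)
for c, name in enumerate(labels.category_names):
    print(f"{name:9s} pooled held-out MCC = {result.pooled_mcc[c]:.3f}")

scfm = compute_scfm(decoder, 0)              # category 0 = Animal
ts = temporal_sparseness(scfm)
print(f"spatial sparseness  = {spatial_sparseness(scfm):.2f}")
print(f"temporal sparseness = {ts['mean_contributing']:.2f}")
```

prints (seed 7):

```
Animal    pooled held-out MCC = 0.958
Building  pooled held-out MCC = 1.000
Plant     pooled held-out MCC = 0.958
Tool      pooled held-out MCC = 0.916
Vehicle   pooled held-out MCC = 0.979
spatial sparseness  = 0.20
temporal sparseness = 0.72
```

The MCCs say the embedded category signal is decoded far above the
chance level of 0 (shuffling the labels drives them to ~0; the chance
MCC is 0 by construction).  The sparseness numbers say 80% of the
neurons contribute to the Animal model while each contributing neuron
is informative over only ~28% of the 2-second window — the
population-coding / temporal-coding signature the pipeline is built to
expose (the generator embedded 75% coding neurons and 75% temporal
sparseness).

The same pipeline is scriptable from the shell:

```bash
memdecode simulate --out data --seed 7
memdecode run --config config.yaml --seed 7
memdecode control --config config.yaml --mode label-shuffle
```

A run directory contains the resolved config, its hash, the serialized
decoder, per-category MCC tables, SCFM exports, sparseness summaries
and importance reports; identical config + seed reproduces every file
bit-exactly.

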