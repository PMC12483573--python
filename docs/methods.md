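# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and the known limits of what the test suite can show.

## Task structure

Eight stimuli form the 2×2×2 factorial of three binary features — leg
(thick/thin), antennae (thick/thin), mandible (shovel/pincer) — encoded
as the three bits of the stimulus id (bit i = feature i; thick/shovel =
0). Three categorization rules each key on one feature; the default
assignment maps task 0/1/2 to leg/antennae/mandible and is configurable
as a permutation.

Schedules are pure functions of a seed:

* **Learning**: 6 blocks × 48 trials, one task per block; the task order
  of blocks 1–3 is a seeded permutation repeated in blocks 4–6; each
  stimulus appears 6× per block (12× per task overall).
* **Test**: 3 blocks × 48 trials with the three tasks interleaved; each
  (task, stimulus) cell appears twice per block (6× overall). No
  feedback.
* **Value task**: 6 blocks × 56 paired-choice trials; each of the
  C(8,2) = 28 unordered pairs appears twice per block, once per
  left/right arrangement (56 = 2 × 28 fixes this pairing scheme; the
  original sampling scheme is not claimed).

Trial timing is recorded as metadata only; nothing computes on it. The
per-trial response-side bit matters only for interpreting the logistic
bias term.

### Reward schedule

Per-stimulus reward probabilities default to

    p = 0.5 + 0.15·s_A + 0.20·s_LM

with `s_A = +1` for thin antennae (else −1) and `s_LM = +1` when the leg
level equals the mandible level (else −1), giving {0.15, 0.45, 0.55,
0.85} twice each. This is the unique two-term construction that meets
the stated feature marginals exactly — thick/thin antennae means
0.35/0.65, both leg and both mandible levels 0.50 — while making the
leg×mandible *combination* (not either feature alone) predictive, and it
produces thin-antennae insects (0.45) worth less than some thick-antennae
insects (0.55). Individual probabilities are overridable by config;
overrides that break the marginals warn rather than fail.

## Synthetic agents

The categorization phases have no canonical generative model, so the
package uses the minimal agent whose parameters map one-to-one onto the
constructs of interest. Per task it holds a belief weight over the six
candidate rules (3 features × 2 polarities), starting uniform. Choice is
a softmax (temperature τ) on the belief-weighted response support, mixed
with a lapse: `P = lapse + (1 − 2·lapse)·σ((s₁ − s₀)/τ)`. Feedback
reveals the correct response; beliefs move toward the consistent-rule
indicator at rate `belief_lr`. While one task is trained, the other two
tasks' beliefs shrink toward uniform at rate `interference` per trial;
at the learning→test boundary all beliefs shrink by the factor
`retention`. This agent is fixture plumbing, not a cognitive claim.

Condition presets (semantic_label / shape_label / no_label) share the
choice parameters (belief_lr 0.18, τ 0.22, lapse 0.05) and differ in
interference (0.0003 / 0.0015 / 0.004 per trial) and retention (0.99 /
0.85 / 0.65). These values were calibrated once so that late-learning
accuracy falls in the 0.75–0.85 band and the qualitative group pattern
emerges (no forgetting with semantic labels; forgetting without, heavier
for earlier-trained tasks); the calibration is a documented config, not
an assertion.

Value-task agents follow the RL equations below generatively with known
parameters (ground truth for recovery). Rewards are drawn only for the
chosen stimulus; the unchosen side's counterfactual outcome is never
sampled. Per-block value snapshots support a 0–100 estimation probe:
estimate = 100 × model-implied stimulus value (object family: `V_S`;
feature family: the mean of the stimulus's three feature-level values)
plus Gaussian noise, clipped to [0, 100].

## RL models and fitting

Four models: {feature, object} × {decay on, off}, with k = 6/7/4/5 free
parameters. Equations as in the README. Numerical choices:

* **Initial values** 0.5 everywhere — the decay attractor and the
  uninformative reward prior.
* **Decay scope**: every value entry not updated on a trial decays,
  including unpresented stimuli/levels.
* **Bounds**: W ∈ [0, 20] (non-negativity is required by the log-weight
  analysis), bias ∈ [−5, 5], α and d ∈ [0, 1]. Configurable.
* **BIC_p penalty** is `k·ln(N)/N` per trial, so the trace sums to the
  global BIC exactly (machine precision); the per-trial trace is
  smoothed for display with a centered 20-trial moving mean with edge
  truncation.
* **Optimizer**: `scipy.optimize.differential_evolution`, population
  15 per parameter, relative tolerance 1e-7, ≤ 1000 generations, L-BFGS-B
  polish, fixed seed per (agent, model). Refits with different optimizer
  seeds reproduce the same optimum to machine precision on this problem,
  so fitting noise is negligible against sampling noise.
* Log feature weights are floored at 1e-6 before the log.
* Trial indices are 0-based internally, 1-based in serialized traces.

The sequential likelihood replay is compiled with numba for speed; an
independent pure-Python replay oracle in the test suite pins it to
1e-12 absolute agreement on short logs.

### What recovery simulations show

At the study size (336 choice trials per agent) the maximum-likelihood
estimator of the generating model is unbiased in the mean but rides a
weight–learning-rate likelihood ridge: a larger W with a smaller α (and
vice versa) yields nearly the same choice probabilities, so `α_reward`
estimates spread widely per agent (median absolute error ≈ 0.15 for
both families at the default generating values; correlation between
fitted α and W ≈ −0.33). Model-family recovery by BIC and the ordinal
weight structure (dominant antennae weight) are essentially perfect.
Conclusions about individual learning-rate values at this sample size
should therefore be treated with caution; conclusions about the model
family and attentional weighting are well supported.

## Recurrent-network stage

The network is an Elman cell (tanh) plus a dense softmax readout,
implemented in numpy with hand-written backpropagation through time and
Adam, which keeps runs bit-reproducible from (config, seed).

Encoding: each trial is 10 timesteps × 8 channels — 5 stimulus channels
(the 3 feature bits, zero-padded to width 5) and 3 one-hot context
channels. Timesteps 0–4 carry only the stimulus (stimulus-first) or only
the context (context-first); timesteps 5–9 carry both. Labels are the
agent's *responses*, not the correct answers. The first 36 trials of
each block train; the last 12 validate. Hidden state resets between
trials; loss is cross-entropy on the final timestep; early stopping
watches validation loss.

Defaults mirror the reference protocol (48 units, lr 1e-4, batch 72,
patience 3, ≤ 10⁴ epochs). A reduced configuration (`SMALL_NET`: 8
units, lr 1e-3, ≤ 2000 epochs, patience 150) is used throughout the
test suite and examples; the higher learning rate makes the validation
loss noisier per epoch, hence the larger patience. An architecture
sweep over {8, 24, 48} units × {2, 10} timesteps is exposed as a config
grid scored by validation loss.

Geometry: representations are the recurrent layer's final-timestep
activation for each of the 24 stimulus×task probes (the final timestep
is the read-out point because both input streams are active there).
Task Separation is the mean over stimuli of the mean pairwise Euclidean
distance across the three task contexts; it is zero iff the task
representations coincide per stimulus, rotation-invariant, and
homogeneous of degree 1 under scaling. Task Specialization compares
each task's 8×8 Euclidean RDM with the binary ground-truth RDM (1 iff
the two stimuli differ on the task-relevant feature) by Spearman
correlation on the strict lower triangle, averaged over tasks; a
zero-variance RDM is dropped from the average with a warning. Note that
the exact complement of the ground-truth RDM is not realizable by any
Euclidean embedding (it would need distinct points at distance zero),
so the −1 reversal bound is checked at the RDM level.

Regressions: OLS of mean training accuracy on mean-centered Task
Separation and Task Specialization plus a labeling indicator (Model 1);
Model 2 adds the two score×labeling interactions; nested models are
compared by the partial F-test. One network is fitted per agent — the
per-agent scores the regressions need cannot come from group-pooled
fits — with pooling available by concatenating logs upstream.

## What the synthetic tests do and do not show

The generators emulate the *structure* of the paradigm (schedules,
reward contingencies, feedback flow) and the qualitative group-level
phenomena, not individual human behavior: no reaction times, no working
memory, no day-2 consolidation, and the categorization agent's
parameters are not fitted to any human data. Passing tests therefore
validate the machinery — schedule balance, likelihood/BIC correctness,
optimizer reliability, metric definitions, regression mechanics, and
recoverability under known ground truth — and the qualitative pattern
generation; they do not reproduce human effect sizes, group means, or
fitted-parameter tables, which require the original behavioral data.

Two reduced-size caveats: at 8 hidden units, the trained-versus-shuffled
specialization contrast is reliable for strongly rule-consistent
response logs but not for noisy cohort-preset agents (whose responses
are only ~70% predictable over all six learning blocks); and the
positive separation→accuracy association emerges across agents spanning
a wide rule-consistency range but not within the deliberately
homogeneous default cohorts, whose accuracy spread is small.
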