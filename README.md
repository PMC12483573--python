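# contlearn

Simulation and analysis toolkit for a three-task continual-learning
paradigm with a downstream value-based decision task: trial-schedule
generation, synthetic participant agents, feature-based vs object-based
reinforcement-learning (RL) model fitting with BIC comparison, and
recurrent-network representational geometry.

## The scientific problem

Humans learn several categorization tasks in sequence with little mutual
interference; artificial networks typically do not. A paradigm for
studying this trains participants on three rules over the same eight
insect-like stimuli — a 2×2×2 factorial of leg thickness, antennae
thickness, and mandible shape — one rule per 48-trial block, six
learning blocks, then three interleaved test blocks with no feedback.
A follow-up value task presents pairs of the same insects with Bernoulli
rewards whose feature marginals are 35% (thick antennae), 65% (thin),
and 50% for each leg and mandible level, so that the antennae partially
predict value but only feature *combinations* predict it fully.

This package reimplements the computational machinery of that paradigm
end to end, with synthetic agents taking the place of participants so
every stage runs without any data download.

### RL models

Choices between stimuli S1, S2 are modeled with a logistic rule.
Feature-based learners carry a value `V_f` per feature level:

    logit P(S1) = Σ_f W_f (V_f,1 − V_f,2) + bias,   f ∈ {Leg, Antennae, Mandible}

object-based learners carry one value per stimulus:

    logit P(S1) = W_o (V_S1 − V_S2) + bias

After feedback `r ∈ {0,1}` the chosen stimulus's entries update with
asymmetric learning rates,

    V ← V + α_reward (1 − V)   if r = 1
    V ← V − α_unreward V       if r = 0

and, in the decay variants, every entry not updated that trial relaxes
toward the uninformative level: `V ← V − d (V − 0.5)`. Models are fitted
per agent by minimizing the sequential negative log likelihood (NLL)
with seeded differential evolution, and compared by

    BIC = 2·NLL + k·ln N,     BIC_p(t) = −2·LL(t) + k·ln(N)/N

where the per-trial decomposition `BIC_p` sums exactly to the global BIC
(k = 6/7 for feature models without/with decay, 4/5 for object models).

### Network geometry

An Elman recurrent network (48 hidden units by default, 10 timesteps per
trial, hidden state reset between trials) is trained per agent to predict
the agent's own responses from a 5-channel stimulus code and a 3-channel
one-hot task context. From the hidden activations of the 24 stimulus ×
task probes we derive **Task Separation** (mean Euclidean distance
between one stimulus's representations across task contexts) and **Task
Specialization** (mean Spearman correlation between each task's 8×8
representational dissimilarity matrix and the binary ground-truth matrix
of its relevant feature), then regress learning accuracy on both scores
and the labeling condition by OLS, with and without interactions.

## Worked example

```python
from contlearn import agents, rl_models, task_design

schedule = task_design.build_value_schedule(seed=1)
rewards = task_design.build_reward_schedule()
generator = agents.GeneratingValueAgent(
    "feature",
    rl_models.ParamVector(w_leg=0.0, w_antennae=4.0, w_mandible=0.0, bias=0.0,
                          alpha_reward=0.4, alpha_unreward=0.3, decay=0.1),
    seed=42,
)
log = agents.simulate_value_agent(schedule, rewards, generator)

fit = rl_models.fit(log, rl_models.ModelSpec("feature", decay=True), seed=5)
print(f"NLL {fit.nll:.3f}  BIC {fit.bic:.3f}")
print(f"w_antennae {fit.params.w_antennae:.2f}  alpha_reward {fit.params.alpha_reward:.2f}")
```

prints

```
NLL 188.929  BIC 418.577
w_antennae 3.89  alpha_reward 0.74
```

i.e. on 336 simulated choices the fitted feature-plus-decay model beats
the chance NLL of `336·ln 2 ≈ 232.9` and recovers the antennae feature
as the dominant attentional weight (3.89 vs the generating 4.0, with the
other weights at 0). The learning rate lands high of its generating
value, illustrating the weight–learning-rate likelihood ridge at this
sample size; across replicate agents the estimator is unbiased and the
median error is near 0.15 (see `docs/methods.md`). This is the recovery
logic used to validate fits before they are trusted on behavioral data.

The `examples/` directory contains one short script per capability
(schedules, cohort simulation, model comparison, network geometry,
full pipeline); each prints the numbers it computes and a line on what
they mean. The `contlearn` command exposes the same stages
(`contlearn run-all --config cfg.yaml --seed 1`).

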