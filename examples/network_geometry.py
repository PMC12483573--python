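"""Train a small recurrent network on an agent's responses and score its
task representation geometry."""

import dataclasses

from contlearn import agents, rnn, task_design

sched = task_design.build_learning_schedule(seed=5)
crisp = agents.CategorizationAgentParams(belief_lr=0.5, softmax_temperature=0.05,
                                         lapse=0.02)
log = agents.simulate_categorization_agent(sched, crisp, seed=5)
print(f"agent learning accuracy: {log['accuracy'].mean():.3f}")

cfg = dataclasses.replace(rnn.SMALL_NET, seed=0)
dataset = rnn.encode_trials(log, "stimulus_first", cfg)
result = rnn.train_network(dataset, cfg)
print(f"network predicts the agent's responses at {result.fit_accuracy:.3f} "
      f"on held-out trials ({result.epochs_run} epochs)")

reps = rnn.probe_representations(result.network, cfg, "stimulus_first")
print(f"task separation:     {rnn.task_separation(reps):.3f} "
      "(mean distance between a stimulus's representations across tasks)")
print(f"task specialization: {rnn.task_specialization(reps):.3f} "
      "(mean Spearman match of per-task RDMs to the feature ground truth; 1 = perfect)")
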