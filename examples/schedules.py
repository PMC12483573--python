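"""Build the trial schedules and the reward table, and show their structure."""

import collections

from contlearn import task_design as td

learn = td.build_learning_schedule(seed=1)
test = td.build_test_schedule(seed=1)
value = td.build_value_schedule(seed=1)

counts = collections.Counter((t.task_id, t.stimulus_id) for t in learn)
print(f"learning: {len(learn)} trials, each (task, insect) cell {set(counts.values())}x")
counts = collections.Counter((t.task_id, t.stimulus_id) for t in test)
print(f"test:     {len(test)} trials, each (task, insect) cell {set(counts.values())}x")
print(f"value:    {len(value)} trials over 6 blocks of 56 (28 pairs x 2 sides)")

rs = td.build_reward_schedule()
print("\nreward probabilities per stimulus:", rs.probabilities)
print(f"antennae marginals: thick {rs.feature_marginal(td.ANTENNAE, 0):.0%}, "
      f"thin {rs.feature_marginal(td.ANTENNAE, 1):.0%}")
print(f"leg/mandible marginals: all {rs.feature_marginal(td.LEG, 0):.0%}")
print("-> only the antennae feature is partially value-predictive on its own;")
print("   the leg x mandible combination carries the rest of the signal.")
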