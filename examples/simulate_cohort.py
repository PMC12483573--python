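"""Simulate labeled and unlabeled cohorts and measure forgetting.

Semantic labels are emulated by higher retention / lower interference in
the rule-belief agent; the unlabeled preset forgets, and earlier-trained
tasks forget more.
"""

from contlearn import agents, stats

for condition in ("semantic_label", "no_label"):
    members = agents.simulate_cohort(30, condition, seed=7)
    table = stats.cohort_accuracy_table([m.log for m in members])
    print(f"{condition:15s} late-learning acc {table['learning_mean'].mean():.3f}  "
          f"test acc {table['test_mean'].mean():.3f}  "
          f"forgetting {table['forgetting'].mean():+.3f}")
print("-> forgetting (learning minus test accuracy) is near zero with semantic"
      " labels and several times larger without them.")

threshold = stats.above_chance_threshold(144, 0.05)
print(f"\nexclusion threshold: {threshold}% correct over the 144 late-learning trials")
print("   (the smallest accuracy significantly above chance by a directional chi-squared test)")
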