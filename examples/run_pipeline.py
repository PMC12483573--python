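"""Run the whole pipeline at demo size: simulate -> fit -> compare ->
estimate -> networks -> geometry."""

import dataclasses

from contlearn import pipeline, rl_models, rnn

config = pipeline.RunConfig(
    seed=1,
    n_agents=3,
    conditions=("semantic_label", "no_label"),
    models=("feature+decay", "object+decay"),
    optimizer=rl_models.OptimizerConfig(popsize=8, tol=1e-4, maxiter=80),
    net=dataclasses.replace(rnn.SMALL_NET, max_epochs=200, early_stop_patience=10),
    output_dir="results/demo",
)
bundle = pipeline.run_pipeline(config)

print("\nmean accuracy per condition:")
print(bundle["accuracy"].groupby("condition")[["learning_mean", "test_mean"]].mean())
for cond, cmp_ in bundle["model_comparison"].items():
    print(f"\n{cond}: best model by mean BIC = {cmp_['best_model']}")
    print(cmp_["table"][["model", "bic_mean", "nll_mean"]].to_string(index=False))
print("\nartifacts written under results/demo/ (TSV logs, fits, geometry scores)")
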