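"""Config-driven end-to-end runner.

A run is a pure function of its configuration: simulate cohorts for the
configured conditions, fit the configured RL models to every agent's
value-task log, compare models, compute value-estimation and accuracy
statistics, train one recurrent network per agent, derive the geometry
scores, and fit the geometry-to-accuracy regressions.  All artifacts are
written as TSV/JSON under the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import agents, rl_models, rnn, stats, task_design

log = logging.getLogger("contlearn.pipeline")

VALID_MODELS = {"object", "object+decay", "feature", "feature+decay"}


@dataclass
class RunConfig:
    seed: int = 0
    n_agents: int = 12
    conditions: tuple[str, ...] = ("semantic_label", "no_label")
    order_condition: str = "stimulus_first"
    models: tuple[str, ...] = ("feature+decay", "object+decay")
    optimizer: rl_models.OptimizerConfig = field(default_factory=rl_models.OptimizerConfig)
    net: rnn.NetConfig = field(default_factory=lambda: rnn.SMALL_NET)
    run_networks: bool = True
    estimate_noise_sd: float = 10.0
    output_dir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["models"] = list(self.models)
        return d


def validate_config(raw: dict | RunConfig) -> tuple[RunConfig, list[str]]:
    """Normalize a raw config dict; returns (config, report of defaulted fields).

    All range/bounds violations are aggregated into a single error.
    """
    if isinstance(raw, RunConfig):
        cfg, defaulted = raw, []
    else:
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        errors = [f"unknown config field {u!r}" for u in sorted(unknown)]
        kwargs = {}
        for key in ("seed", "n_agents", "order_condition", "run_networks",
                    "estimate_noise_sd", "output_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "conditions" in raw:
            kwargs["conditions"] = tuple(raw["conditions"])
        if "models" in raw:
            kwargs["models"] = tuple(raw["models"])
        if "optimizer" in raw:
            kwargs["optimizer"] = rl_models.OptimizerConfig(**raw["optimizer"])
        if "net" in raw:
            kwargs["net"] = rnn.NetConfig(**raw["net"])
        if errors:
            raise ValueError("; ".join(errors))
        cfg = RunConfig(**kwargs)
        defaulted = sorted({f.name for f in dataclasses.fields(RunConfig)} - set(kwargs))
    errors = []
    if cfg.n_agents < 1:
        errors.append(f"n_agents must be >= 1, got {cfg.n_agents}")
    if not cfg.conditions:
        errors.append("conditions must be non-empty")
    for c in cfg.conditions:
        if c not in agents.CONDITIONS:
            errors.append(f"unknown condition {c!r}; valid: {sorted(agents.CONDITIONS)}")
    for m in cfg.models:
        if m not in VALID_MODELS:
            errors.append(f"unknown model {m!r}; valid: {sorted(VALID_MODELS)}")
    if cfg.order_condition not in agents.ORDER_CONDITIONS:
        errors.append(f"unknown order_condition {cfg.order_condition!r}; "
                      f"valid: {sorted(agents.ORDER_CONDITIONS)}")
    if cfg.estimate_noise_sd < 0:
        errors.append("estimate_noise_sd must be >= 0")
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return cfg, [f"defaulted: {d}" for d in defaulted]


def load_config(path: str | Path) -> tuple[RunConfig, list[str]]:
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    return validate_config(raw or {})


def _model_spec(name: str) -> rl_models.ModelSpec:
    family, _, tail = name.partition("+")
    return rl_models.ModelSpec(family, decay=tail == "decay")


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute every stage; returns the result bundle and writes artifacts."""
    cfg, _ = validate_config(config)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": cfg.to_dict()}
    t0 = time.time()

    # --- stage 1: simulate cohorts -------------------------------------
    log.info("stage simulate: %d agents x %s", cfg.n_agents, cfg.conditions)
    cohorts = {}
    for ci, cond in enumerate(cfg.conditions):
        cohorts[cond] = agents.simulate_cohort(
            cfg.n_agents, cond, seed=cfg.seed + 1000 * ci,
            order_condition=cfg.order_condition, include_value_phase=True,
        )
    all_logs = pd.concat([m.log for cond in cohorts for m in cohorts[cond]])
    all_logs.to_csv(out / "categorization_logs.tsv", sep="\t", index=False)

    # --- stage 2: accuracy / forgetting stats --------------------------
    acc_table = stats.cohort_accuracy_table(
        [m.log for cond in cohorts for m in cohorts[cond]]
    )
    acc_table.to_csv(out / "accuracy_summary.tsv", sep="\t", index=False)
    bundle["accuracy"] = acc_table

    # --- stage 3: RL fits + comparison ---------------------------------
    log.info("stage fit: models %s", cfg.models)
    specs = [_model_spec(m) for m in cfg.models]
    rsched = task_design.build_reward_schedule()
    fit_rows = []
    comparisons = {}
    for cond, members in cohorts.items():
        fits = {}
        for m in members:
            per_agent = {}
            for spec in specs:
                fr = rl_models.fit(m.value_log, spec,
                                   optimizer_config=cfg.optimizer,
                                   seed=cfg.seed + 13 * m.agent_id + spec.k)
                per_agent[spec.name] = fr
                fit_rows.append({"condition": cond, "agent_id": m.agent_id,
                                 **fr.to_dict()["params"], "model": spec.name,
                                 "nll": fr.nll, "bic": fr.bic,
                                 "converged": fr.converged})
            fits[m.agent_id] = per_agent
        comparisons[cond] = rl_models.compare_models(
            fits, contrasts=[(specs[0].name, specs[-1].name)] if len(specs) > 1 else []
        )
        comparisons[cond]["table"].to_csv(out / f"model_comparison_{cond}.tsv",
                                          sep="\t", index=False)
    pd.DataFrame(fit_rows).to_csv(out / "rl_fits.tsv", sep="\t", index=False)
    bundle["model_comparison"] = comparisons

    # --- stage 4: value-estimation distances ---------------------------
    est_rows = []
    for cond, members in cohorts.items():
        for m in members:
            states = m.value_log.attrs["block_states"]
            family = m.value_log.attrs["family"]
            for block, values in states.items():
                est = agents.simulate_value_estimates(
                    values, cfg.estimate_noise_sd, cfg.seed + 7 * m.agent_id + block,
                    family=family,
                )
                est_rows.append({
                    "condition": cond, "agent_id": m.agent_id, "block": block,
                    "object_distance": stats.estimate_distance(est, rsched, "object_based"),
                    "feature_distance": stats.estimate_distance(est, rsched, "feature_based"),
                })
    est_table = pd.DataFrame(est_rows)
    est_table.to_csv(out / "value_estimates.tsv", sep="\t", index=False)
    bundle["value_estimates"] = est_table

    # --- stage 5: networks + geometry ----------------------------------
    geometry = pd.DataFrame()
    if cfg.run_networks:
        log.info("stage geometry: %d nets of %d units",
                 sum(len(v) for v in cohorts.values()), cfg.net.hidden_units)
        geo_rows = []
        for cond, members in cohorts.items():
            for m in members:
                ds = rnn.encode_trials(m.log, cfg.order_condition, cfg.net)
                net_cfg = dataclasses.replace(
                    cfg.net, seed=cfg.seed + 101 * m.agent_id + len(cond))
                tr = rnn.train_network(ds, net_cfg)
                scores = rnn.geometry_scores(tr.network, tr.fit_accuracy,
                                             net_cfg, cfg.order_condition)
                prof = stats.accuracy_profile(m.log)
                geo_rows.append({"condition": cond, "agent_id": m.agent_id,
                                 "labeling": int(cond == "semantic_label"),
                                 "accuracy": prof.learning_mean, **scores})
        geometry = pd.DataFrame(geo_rows)
        geometry.to_csv(out / "geometry.tsv", sep="\t", index=False)
        bundle["geometry"] = geometry

        # --- stage 6: geometry regressions -----------------------------
        if geometry["labeling"].nunique() > 1 and \
                geometry.groupby("labeling").size().min() >= 10:
            reg = rnn.fit_geometry_regressions(geometry)
            (out / "geometry_regressions.json").write_text(json.dumps(
                {k: v for k, v in reg.items() if not k.startswith("model")}, indent=2))
            bundle["regressions"] = reg

    (out / "run_manifest.json").write_text(json.dumps(
        {"config": cfg.to_dict(), "elapsed_s": time.time() - t0}, indent=2))
    log.info("pipeline done in %.1f s", time.time() - t0)
    return bundle
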