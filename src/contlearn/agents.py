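"""Synthetic participant-like agents for every pipeline stage.

Two families of agents are generated:

* a rule-belief learner for the categorization phases, holding per task a
  belief weight over the six candidate rules (3 features x 2 polarities),
  choosing by softmax with lapse, and degraded by cross-task interference
  while other tasks are trained and by a retention factor at the
  learning-to-test boundary; and
* value-task agents that follow the feature-based or object-based
  reinforcement-learning equations generatively with known parameters, so
  downstream fits can be checked against ground truth.

The belief learner is artifact plumbing: its parameters map onto the
constructs of interest (interference, retention) but it makes no
cognitive claim.  Cohort presets shift these parameters to emulate the
qualitative group-level patterns (semantic labels protecting test-phase
accuracy; their absence producing forgetting that disproportionately
affects earlier-trained tasks).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import rl_models, task_design
from .rl_models import ModelSpec, ParamVector, ValueState
from .task_design import RewardSchedule, Schedule, TaskRule

CONDITIONS = ("semantic_label", "no_label", "shape_label")
ORDER_CONDITIONS = ("stimulus_first", "context_first")


@dataclass(frozen=True)
class CategorizationAgentParams:
    """Parameters of the rule-belief learner.

    belief_lr
        step size of the belief update toward feedback-consistent rules,
        in (0, 1].
    softmax_temperature
        temperature of the response softmax over rule-weighted support;
        lower = more deterministic.
    lapse
        probability mass of uniform random responding, in [0, 0.5).
    interference
        per-trial shrinkage of the *other* tasks' beliefs toward uniform
        while one task is being trained, in [0, 1].
    retention
        belief scaling at the learning-to-test transition, in [0, 1];
        1 = perfect retention.
    """

    belief_lr: float = 0.18
    softmax_temperature: float = 0.22
    lapse: float = 0.05
    interference: float = 0.0
    retention: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.belief_lr <= 1.0:
            raise ValueError("belief_lr must be in (0, 1]")
        if self.softmax_temperature <= 0:
            raise ValueError("softmax_temperature must be positive")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must be in [0, 0.5)")
        if not 0.0 <= self.interference <= 1.0:
            raise ValueError("interference must be in [0, 1]")
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("retention must be in [0, 1]")


#: condition presets, calibrated so late-learning accuracy sits in the
#: 0.75-0.85 band; semantic labels raise retention and damp interference
CONDITION_PRESETS: dict[str, CategorizationAgentParams] = {
    "semantic_label": CategorizationAgentParams(
        belief_lr=0.18, softmax_temperature=0.22, lapse=0.05,
        interference=0.0003, retention=0.99,
    ),
    "shape_label": CategorizationAgentParams(
        belief_lr=0.18, softmax_temperature=0.22, lapse=0.05,
        interference=0.0015, retention=0.85,
    ),
    "no_label": CategorizationAgentParams(
        belief_lr=0.18, softmax_temperature=0.22, lapse=0.05,
        interference=0.004, retention=0.65,
    ),
}

# the 6 candidate rules: (feature, polarity)
_CANDIDATE_RULES = [(f, p) for f in range(3) for p in (0, 1)]
_UNIFORM_BELIEF = 1.0 / len(_CANDIDATE_RULES)


@dataclass(frozen=True)
class GeneratingValueAgent:
    """A value-task agent with known generating parameters."""

    family: str
    params: ParamVector
    decay: bool = True
    seed: int = 0

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(self.family, self.decay)


def _rule_predictions(stimulus_id: int) -> np.ndarray:
    levels = task_design.FEATURE_LEVELS[stimulus_id]
    return np.array([levels[f] ^ p for f, p in _CANDIDATE_RULES], dtype=np.float64)


def simulate_categorization_agent(
    schedule: Schedule,
    params: CategorizationAgentParams,
    seed: int,
    task_rules: Sequence[TaskRule] | None = None,
) -> pd.DataFrame:
    """Simulate one agent through a learning and/or test schedule.

    Beliefs start uniform per task.  In the learning phase feedback tells
    the agent the correct response, reinforcing consistent rules; beliefs
    of the other two tasks shrink toward uniform at the interference
    rate.  At the first test trial all beliefs shrink by the retention
    factor.  Test trials give no feedback and cause no updates.
    """
    rules = list(task_rules) if task_rules is not None else task_design.default_task_rules()
    rng = np.random.default_rng(seed)
    beliefs = np.full((3, 6), _UNIFORM_BELIEF)
    rows = []
    retention_applied = False
    for trial in schedule:
        if trial.phase == "test" and not retention_applied:
            beliefs = _UNIFORM_BELIEF + params.retention * (beliefs - _UNIFORM_BELIEF)
            retention_applied = True
        task = trial.task_id
        preds = _rule_predictions(trial.stimulus_id)
        support1 = float(beliefs[task] @ preds)  # belief-weighted vote for response 1
        support0 = float(beliefs[task] @ (1.0 - preds))
        z = (support1 - support0) / params.softmax_temperature
        p1 = 1.0 / (1.0 + np.exp(-z))
        p1 = params.lapse + (1.0 - 2.0 * params.lapse) * p1
        response = int(rng.random() < p1)
        correct = task_design.correct_response(rules[task], trial.stimulus_id)
        is_correct = int(response == correct)
        feedback = is_correct if trial.phase == "learning" else None
        if trial.phase == "learning":
            consistent = (preds == correct).astype(np.float64)
            target = consistent / consistent.sum()
            beliefs[task] += params.belief_lr * (target - beliefs[task])
            for other in range(3):
                if other != task:
                    beliefs[other] += params.interference * (_UNIFORM_BELIEF - beliefs[other])
        rows.append(
            {
                "trial_index": trial.trial_index,
                "phase": trial.phase,
                "block": trial.block,
                "task_id": task,
                "stimulus_id": trial.stimulus_id,
                "side": trial.side,
                "response": response,
                "correct_response": correct,
                "accuracy": is_correct,
                "feedback": feedback,
            }
        )
    return pd.DataFrame(rows)


def simulate_value_agent(
    value_schedule: Schedule,
    reward_schedule: RewardSchedule,
    agent: GeneratingValueAgent,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a value-task response log from the agent's own equations.

    Each trial: P(left) from the family's logistic rule, choice drawn,
    reward ~ Bernoulli(reward probability of the chosen stimulus), chosen
    update applied, then (decay variants) decay of the untouched entries.
    Only the chosen stimulus's reward is ever drawn.
    """
    rng = np.random.default_rng(agent.seed if seed is None else seed)
    state = ValueState(agent.family)
    d = agent.params.decay if agent.decay else None
    rows = []
    block_states: dict[int, np.ndarray] = {}
    prev_block = None
    for trial in value_schedule:
        if prev_block is not None and trial.block != prev_block:
            block_states[prev_block] = state.values.copy()
        prev_block = trial.block
        p_left = rl_models.choice_probability(
            state, trial.left_stimulus_id, trial.right_stimulus_id, agent.params
        )
        response = int(rng.random() >= p_left)  # 0 = left, 1 = right
        chosen = trial.left_stimulus_id if response == 0 else trial.right_stimulus_id
        unchosen = trial.right_stimulus_id if response == 0 else trial.left_stimulus_id
        reward = int(rng.random() < reward_schedule[chosen])
        # higher-value choice per the schedule counts as "accurate"
        acc = int(reward_schedule[chosen] >= reward_schedule[unchosen])
        updated = rl_models.update_chosen(
            state, chosen, reward, agent.params.alpha_reward, agent.params.alpha_unreward
        )
        if d is not None:
            rl_models.apply_decay(state, updated, d)
        rows.append(
            {
                "trial_index": trial.trial_index,
                "phase": "value",
                "block": trial.block,
                "left_stimulus_id": trial.left_stimulus_id,
                "right_stimulus_id": trial.right_stimulus_id,
                "response": response,
                "chosen_stimulus_id": chosen,
                "reward": reward,
                "accuracy": acc,
            }
        )
    if prev_block is not None:
        block_states[prev_block] = state.values.copy()
    log = pd.DataFrame(rows)
    log.attrs["block_states"] = block_states
    log.attrs["family"] = agent.family
    return log


def simulate_value_estimates(
    agent_state: ValueState | np.ndarray,
    noise_sd: float,
    seed: int,
    family: str | None = None,
) -> np.ndarray:
    """0-100 value estimates of the 8 stimuli from a terminal value state.

    Estimate = 100 x model-implied stimulus value (object family: V_S;
    feature family: mean of the stimulus's three feature-level values)
    plus Gaussian noise, clipped to [0, 100].
    """
    if isinstance(agent_state, np.ndarray):
        if family is None:
            family = "feature" if agent_state.ndim == 2 else "object"
        state = ValueState(family)
        state.values = agent_state.astype(np.float64)
    else:
        state = agent_state
    rng = np.random.default_rng(seed)
    est = np.array([100.0 * state.stimulus_value(s) for s in range(task_design.N_STIMULI)])
    est = est + rng.normal(0.0, noise_sd, size=est.shape)
    return np.clip(est, 0.0, 100.0)


@dataclass
class ParamDistributions:
    """Per-agent sampling of categorization parameters around a preset.

    Each agent's belief_lr/lapse are jittered log-normally / truncated-
    normally around the preset to give the cohort realistic heterogeneity.
    """

    belief_lr_sd: float = 0.25  # multiplicative (log-normal sigma)
    lapse_sd: float = 0.03
    retention_sd: float = 0.05
    interference_sd_frac: float = 0.5

    def sample(self, preset: CategorizationAgentParams, rng: np.random.Generator
               ) -> CategorizationAgentParams:
        lr = float(np.clip(preset.belief_lr * np.exp(rng.normal(0, self.belief_lr_sd)),
                           1e-3, 1.0))
        lapse = float(np.clip(rng.normal(preset.lapse, self.lapse_sd), 0.0, 0.49))
        retention = float(np.clip(rng.normal(preset.retention, self.retention_sd), 0.0, 1.0))
        interference = float(
            np.clip(rng.normal(preset.interference,
                               self.interference_sd_frac * preset.interference), 0.0, 1.0)
        )
        return replace(preset, belief_lr=lr, lapse=lapse,
                       retention=retention, interference=interference)


@dataclass
class CohortMember:
    agent_id: int
    condition: str
    order_condition: str
    params: CategorizationAgentParams
    log: pd.DataFrame  # categorization phases (learning + test)
    value_log: pd.DataFrame | None = None


def simulate_cohort(
    n_agents: int,
    condition: str,
    param_distributions: ParamDistributions | None = None,
    seed: int = 0,
    order_condition: str = "stimulus_first",
    include_value_phase: bool = False,
) -> list[CohortMember]:
    """Simulate a cohort of agents under one condition preset.

    Each agent gets its own sampled parameters and its own seeded
    schedules (task order counterbalanced by seed), runs the learning and
    test phases, and optionally the value-based decision-making phase
    with an RL agent whose weights reflect the condition (semantic labels
    ~ balanced feature weights; no labels ~ antennae-dominated).
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    if order_condition not in ORDER_CONDITIONS:
        raise ValueError(f"order_condition must be one of {ORDER_CONDITIONS}")
    preset = CONDITION_PRESETS[condition]
    dists = param_distributions or ParamDistributions()
    master = np.random.default_rng(seed)
    members = []
    for i in range(n_agents):
        agent_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(agent_seed)
        params = dists.sample(preset, rng)
        learn = task_design.build_learning_schedule(agent_seed, order_condition)
        test = task_design.build_test_schedule(agent_seed + 1, order_condition)
        sched = Schedule(learn.trials + test.trials, agent_seed, order_condition)
        log = simulate_categorization_agent(sched, params, agent_seed + 2)
        log["agent_id"] = i
        log["condition"] = condition
        log["order_condition"] = order_condition
        member = CohortMember(i, condition, order_condition, params, log)
        if include_value_phase:
            member.value_log = _value_phase_for(condition, agent_seed, i)
        members.append(member)
    return members


def _value_phase_for(condition: str, agent_seed: int, agent_id: int) -> pd.DataFrame:
    vsched = task_design.build_value_schedule(agent_seed + 3)
    rsched = task_design.build_reward_schedule()
    if condition == "semantic_label":
        pv = ParamVector(w_leg=3.0, w_antennae=3.0, w_mandible=3.0, bias=0.0,
                         alpha_reward=0.35, alpha_unreward=0.25, decay=0.08)
    else:
        pv = ParamVector(w_leg=0.8, w_antennae=5.0, w_mandible=0.8, bias=0.0,
                         alpha_reward=0.35, alpha_unreward=0.25, decay=0.08)
    agent = GeneratingValueAgent("feature", pv, decay=True, seed=agent_seed + 4)
    vlog = simulate_value_agent(vsched, rsched, agent)
    vlog["agent_id"] = agent_id
    vlog["condition"] = condition
    return vlog


def generating_value_cohort(
    n_agents: int,
    family: str,
    seed: int,
    params: ParamVector | None = None,
    decay: bool = True,
) -> list[tuple[GeneratingValueAgent, pd.DataFrame]]:
    """Value-task logs from agents with known parameters, for recovery tests."""
    if params is None:
        if family == "feature":
            params = ParamVector(w_leg=0.0, w_antennae=4.0, w_mandible=0.0, bias=0.0,
                                 alpha_reward=0.4, alpha_unreward=0.3, decay=0.1)
        else:
            params = ParamVector(w_object=5.0, bias=0.0,
                                 alpha_reward=0.4, alpha_unreward=0.3, decay=0.1)
    master = np.random.default_rng(seed)
    rsched = task_design.build_reward_schedule()
    out = []
    for i in range(n_agents):
        s = int(master.integers(2**31 - 1))
        vsched = task_design.build_value_schedule(s)
        agent = GeneratingValueAgent(family, params, decay=decay, seed=s + 1)
        log = simulate_value_agent(vsched, rsched, agent)
        log["agent_id"] = i
        out.append((agent, log))
    return out


def write_response_log(log: pd.DataFrame, path, manifest: dict | None = None) -> None:
    """TSV response log + JSON manifest of generating parameters."""
    import json
    from pathlib import Path

    path = Path(path)
    log.to_csv(path, sep="\t", index=False)
    if manifest is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=2))
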