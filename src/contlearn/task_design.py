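"""Stimulus space, task rules, and trial/reward schedule generators.

The paradigm uses eight insect-like stimuli built from the factorial
combination of three binary features (leg thickness, antennae thickness,
mandible shape).  Three categorization tasks each key on exactly one
feature.  Learning runs six blocks of 48 trials (one task per block, the
block order of the first three tasks repeated once); a test phase runs
three blocks of 48 trials with tasks interleaved; a value-based
decision-making phase runs six blocks of 56 paired-choice trials with
Bernoulli rewards drawn from a per-stimulus probability table whose
feature marginals are 35%/65% (thick/thin antennae) and 50% (leg,
mandible).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

N_FEATURES = 3
N_STIMULI = 8
N_TASKS = 3

FEATURE_NAMES = ("leg", "antennae", "mandible")
#: feature-level names, index 0/1 per feature (thick=0/thin=1, shovel=0/pincer=1)
LEVEL_NAMES = (("thick", "thin"), ("thick", "thin"), ("shovel", "pincer"))

LEG, ANTENNAE, MANDIBLE = 0, 1, 2

LEARNING_BLOCKS = 6
TEST_BLOCKS = 3
TRIALS_PER_BLOCK = 48
VALUE_BLOCKS = 6
VALUE_TRIALS_PER_BLOCK = 56


@dataclass(frozen=True)
class Stimulus:
    """One of the 8 factorial stimuli; ``features[i]`` is the level bit of feature i."""

    id: int
    features: tuple[int, int, int]

    def level(self, feature: int) -> int:
        return self.features[feature]


@dataclass(frozen=True)
class TaskRule:
    """A categorization task keyed on one feature.

    ``polarity`` maps the feature level to the response bit: response =
    level XOR polarity (polarity 0 = identity).
    """

    task_id: int
    relevant_feature: int
    polarity: int = 0


def enumerate_stimuli() -> list[Stimulus]:
    """The 8 stimuli; stimulus id bit i encodes feature i's level."""
    return [
        Stimulus(id=i, features=((i >> 0) & 1, (i >> 1) & 1, (i >> 2) & 1))
        for i in range(N_STIMULI)
    ]


STIMULI = enumerate_stimuli()
#: (8, 3) int array of feature levels, row = stimulus id
FEATURE_LEVELS = np.array([s.features for s in STIMULI], dtype=np.int64)


def default_task_rules(feature_permutation: Sequence[int] = (0, 1, 2)) -> list[TaskRule]:
    """Three rules covering the three features once each.

    ``feature_permutation`` maps task_id -> relevant feature, exposing the
    counterbalancing of the feature-to-task assignment.
    """
    perm = tuple(feature_permutation)
    if sorted(perm) != [0, 1, 2]:
        raise ValueError(f"feature_permutation must permute (0,1,2), got {perm!r}")
    return [TaskRule(task_id=t, relevant_feature=perm[t]) for t in range(N_TASKS)]


def correct_response(rule: TaskRule, stimulus: Stimulus | int) -> int:
    """Response bit the rule prescribes for the stimulus."""
    if isinstance(stimulus, int):
        stimulus = STIMULI[stimulus]
    return stimulus.features[rule.relevant_feature] ^ rule.polarity


@dataclass(frozen=True)
class Trial:
    trial_index: int
    phase: str  # "learning" | "test" | "value"
    block: int  # 1-based
    task_id: int = -1  # -1 for value trials
    stimulus_id: int = -1  # categorization trials
    left_stimulus_id: int = -1  # value trials
    right_stimulus_id: int = -1
    side: int = 0  # response-label side assignment bit (metadata)


@dataclass
class Schedule:
    """Ordered trial list plus the config that generated it."""

    trials: list[Trial]
    seed: int
    order_condition: str = "stimulus_first"
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.trials])

    def to_tsv(self, path: str | Path) -> None:
        """One row per trial; JSON sidecar with seed + config."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        sidecar = {"seed": self.seed, "order_condition": self.order_condition, **self.meta}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def build_learning_schedule(seed: int, order_condition: str = "stimulus_first") -> Schedule:
    """288 learning trials: 6 blocks x 48, one task per block.

    The task order over blocks 1-3 is a seeded random permutation of the
    three tasks; blocks 4-6 repeat it.  Within each block every stimulus
    appears 6 times in shuffled order, so each (task, insect) pair occurs
    12 times overall.
    """
    _check_order_condition(order_condition)
    rng = np.random.default_rng(seed)
    task_order = rng.permutation(N_TASKS)
    trials: list[Trial] = []
    idx = 0
    for block in range(1, LEARNING_BLOCKS + 1):
        task = int(task_order[(block - 1) % N_TASKS])
        stims = np.repeat(np.arange(N_STIMULI), TRIALS_PER_BLOCK // N_STIMULI)
        rng.shuffle(stims)
        for s in stims:
            trials.append(
                Trial(
                    trial_index=idx,
                    phase="learning",
                    block=block,
                    task_id=task,
                    stimulus_id=int(s),
                    side=int(rng.integers(2)),
                )
            )
            idx += 1
    return Schedule(trials, seed, order_condition, meta={"task_order": task_order.tolist()})


def build_test_schedule(seed: int, order_condition: str = "stimulus_first") -> Schedule:
    """144 test trials: 3 blocks x 48 with the three tasks interleaved.

    Per block each task contributes 16 trials (each insect twice); no
    feedback is given in this phase.
    """
    _check_order_condition(order_condition)
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    idx = 0
    for block in range(LEARNING_BLOCKS + 1, LEARNING_BLOCKS + TEST_BLOCKS + 1):
        cells = [(t, s) for t in range(N_TASKS) for s in range(N_STIMULI) for _ in range(2)]
        order = rng.permutation(len(cells))
        for j in order:
            task, s = cells[j]
            trials.append(
                Trial(
                    trial_index=idx,
                    phase="test",
                    block=block,
                    task_id=task,
                    stimulus_id=s,
                    side=int(rng.integers(2)),
                )
            )
            idx += 1
    return Schedule(trials, seed, order_condition)


def build_value_schedule(seed: int) -> Schedule:
    """6 blocks x 56 paired-choice trials.

    Per block each of the 28 unordered stimulus pairs appears exactly
    twice, once per left/right arrangement, in shuffled order.
    """
    rng = np.random.default_rng(seed)
    pairs = [(a, b) for a in range(N_STIMULI) for b in range(a + 1, N_STIMULI)]
    trials: list[Trial] = []
    idx = 0
    for block in range(1, VALUE_BLOCKS + 1):
        arrangements = [(a, b) for a, b in pairs] + [(b, a) for a, b in pairs]
        order = rng.permutation(len(arrangements))
        for j in order:
            left, right = arrangements[j]
            trials.append(
                Trial(
                    trial_index=idx,
                    phase="value",
                    block=block,
                    left_stimulus_id=left,
                    right_stimulus_id=right,
                )
            )
            idx += 1
    return Schedule(trials, seed, meta={"n_pairs": len(pairs)})


@dataclass(frozen=True)
class RewardSchedule:
    """Per-stimulus Bernoulli reward probabilities for the value task."""

    probabilities: tuple[float, ...]

    def __post_init__(self):
        if len(self.probabilities) != N_STIMULI:
            raise ValueError("need one probability per stimulus")
        for p in self.probabilities:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"reward probability {p} outside [0, 1]")

    def __getitem__(self, stimulus_id: int) -> float:
        return self.probabilities[stimulus_id]

    def feature_marginal(self, feature: int, level: int) -> float:
        mask = FEATURE_LEVELS[:, feature] == level
        return float(np.mean(np.asarray(self.probabilities)[mask]))


def build_reward_schedule(
    config: Mapping[int, float] | Sequence[float] | None = None,
) -> RewardSchedule:
    """Default reward table p = 0.5 + 0.15*s_A + 0.20*s_LM.

    s_A = +1 for thin antennae else -1; s_LM = +1 if the leg level equals
    the mandible level else -1, giving the values {0.15, 0.45, 0.55, 0.85}
    twice each.  The marginals are 35% (thick antennae), 65% (thin), and
    50% for each leg and mandible level.  ``config`` may override
    per-stimulus probabilities (dict id->p or a full 8-sequence); overrides
    breaking the marginal constraints warn but do not fail.
    """
    probs = []
    for s in STIMULI:
        s_a = 1.0 if s.features[ANTENNAE] == 1 else -1.0
        s_lm = 1.0 if s.features[LEG] == s.features[MANDIBLE] else -1.0
        probs.append(0.5 + 0.15 * s_a + 0.20 * s_lm)
    if config is not None:
        if isinstance(config, Mapping):
            for k, v in config.items():
                probs[int(k)] = float(v)
        else:
            probs = [float(v) for v in config]
    sched = RewardSchedule(tuple(probs))
    expected = {(ANTENNAE, 0): 0.35, (ANTENNAE, 1): 0.65, (LEG, 0): 0.50,
                (LEG, 1): 0.50, (MANDIBLE, 0): 0.50, (MANDIBLE, 1): 0.50}
    for (f, lvl), target in expected.items():
        if abs(sched.feature_marginal(f, lvl) - target) > 1e-12:
            warnings.warn(
                f"reward schedule override breaks the {FEATURE_NAMES[f]}="
                f"{LEVEL_NAMES[f][lvl]} marginal ({sched.feature_marginal(f, lvl):.3f}"
                f" vs {target})",
                stacklevel=2,
            )
            break
    return sched


def _check_order_condition(order_condition: str) -> None:
    if order_condition not in ("stimulus_first", "context_first"):
        raise ValueError(
            f"order_condition must be 'stimulus_first' or 'context_first', got {order_condition!r}"
        )


def read_schedule_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
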