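"""Accuracy aggregation, exclusion thresholding, value-estimation
distances, and the cross-phase correlation comparison.

These are the plumbing-level statistics of the paradigm: per-block
accuracy profiles and their learning-vs-test (forgetting) contrast, the
chi-squared above-chance exclusion threshold, mean absolute distances of
0-100 value estimates from object-based or feature-based ground truths,
and the Fisher-z comparison of two independent Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task_design import ANTENNAE, FEATURE_LEVELS, N_STIMULI, RewardSchedule

LEARNING_BLOCKS = (4, 5, 6)
TEST_BLOCKS = (7, 8, 9)


def above_chance_threshold(n_trials: int, alpha: float = 0.05, return_count: bool = False):
    """Smallest above-chance accuracy (integer percent) detectable by a
    directional 1-df chi-squared goodness-of-fit test against (n/2, n/2).

    Scans counts k > n/2 for the first with a directional p below alpha
    (the two-sided chi-squared tail halved, equivalently a one-sided
    binomial z-test).  At n=144, alpha=.05 this gives k=82, i.e. 57%.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    expected = n_trials / 2.0
    for k in range(n_trials // 2 + 1, n_trials + 1):
        chi2 = (k - expected) ** 2 / expected + ((n_trials - k) - expected) ** 2 / expected
        p = sps.chi2.sf(chi2, df=1) / 2.0
        if p < alpha:
            pct = int(round(100.0 * k / n_trials))
            return (pct, k) if return_count else pct
    raise ValueError(f"no count reaches significance at n={n_trials}, alpha={alpha}")


@dataclass
class AccuracyProfile:
    """Per-agent per-block accuracy over the 9 categorization blocks."""

    block_accuracy: dict[int, float]
    task_block_accuracy: dict[tuple[int, int], float]  # (training-order task, block)
    task_training_order: list[int]  # task_id trained first, second, third

    @property
    def learning_mean(self) -> float:
        return float(np.mean([self.block_accuracy[b] for b in LEARNING_BLOCKS]))

    @property
    def test_mean(self) -> float:
        return float(np.mean([self.block_accuracy[b] for b in TEST_BLOCKS]))


def accuracy_profile(log: pd.DataFrame) -> AccuracyProfile:
    """Build an accuracy profile from a categorization response log."""
    needed = {"block", "task_id", "accuracy", "phase"}
    if not needed.issubset(log.columns):
        raise ValueError(f"log missing columns {needed - set(log.columns)}")
    block_acc = log.groupby("block")["accuracy"].mean().to_dict()
    # training order: task of learning blocks 1..3
    order = [int(log.loc[log["block"] == b, "task_id"].iloc[0]) for b in (1, 2, 3)]
    task_block = {
        (order.index(int(t)) + 1, int(b)): float(a)
        for (b, t), a in log.groupby(["block", "task_id"])["accuracy"].mean().items()
    }
    return AccuracyProfile({int(k): float(v) for k, v in block_acc.items()}, task_block, order)


def phase_contrast(profile: AccuracyProfile) -> dict:
    """Forgetting = late-learning mean (blocks 4-6) minus test mean (blocks 7-9).

    Per-task scores index tasks by training order (task 1 = first-trained).
    """
    missing = [b for b in LEARNING_BLOCKS + TEST_BLOCKS if b not in profile.block_accuracy]
    if missing:
        raise ValueError(f"profile missing blocks {missing}")
    out = {"forgetting": profile.learning_mean - profile.test_mean}
    for pos in (1, 2, 3):
        learn = [profile.task_block_accuracy[(pos, b)]
                 for b in LEARNING_BLOCKS if (pos, b) in profile.task_block_accuracy]
        test = [profile.task_block_accuracy[(pos, b)]
                for b in TEST_BLOCKS if (pos, b) in profile.task_block_accuracy]
        if learn and test:
            out[f"task{pos}_forgetting"] = float(np.mean(learn) - np.mean(test))
    return out


def estimate_distance(
    estimates: np.ndarray, reward_schedule: RewardSchedule, mode: str = "object_based"
) -> float:
    """Mean absolute distance of 0-100 estimates from ground-truth values.

    object_based: |estimate - 100*p(stimulus)|.  feature_based: distance
    to the mean reward probability over stimuli sharing the antennae
    level (35 for thick, 65 for thin on the default schedule).
    """
    est = np.asarray(estimates, dtype=np.float64)
    if est.shape[-1] != N_STIMULI:
        raise ValueError("estimates must have one column per stimulus")
    if np.any((est < 0) | (est > 100)):
        raise ValueError("estimates must lie in [0, 100]")
    if mode == "object_based":
        truth = 100.0 * np.asarray(reward_schedule.probabilities)
    elif mode == "feature_based":
        truth = np.array(
            [100.0 * reward_schedule.feature_marginal(ANTENNAE, FEATURE_LEVELS[s, ANTENNAE])
             for s in range(N_STIMULI)]
        )
    else:
        raise ValueError("mode must be 'object_based' or 'feature_based'")
    return float(np.mean(np.abs(est - truth)))


def correlation_compare(x1, y1, x2, y2) -> dict:
    """Compare two independent Pearson correlations via Fisher's z.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided
    normal p-value.
    """
    x1, y1, x2, y2 = (np.asarray(a, dtype=np.float64) for a in (x1, y1, x2, y2))
    for a in (x1, y1, x2, y2):
        if a.std() == 0:
            raise ValueError("zero-variance input")
    if len(x1) < 4 or len(x2) < 4:
        raise ValueError("each group needs n >= 4")
    r1 = float(sps.pearsonr(x1, y1).statistic)
    r2 = float(sps.pearsonr(x2, y2).statistic)
    z = fisher_z_from_r(r1, len(x1), r2, len(x2))
    return {"r1": r1, "r2": r2, "z": z, "p": 2.0 * float(sps.norm.sf(abs(z)))}


def fisher_z_from_r(r1: float, n1: int, r2: float, n2: int) -> float:
    """Fisher z statistic for the difference of two independent correlations."""
    if n1 < 4 or n2 < 4:
        raise ValueError("each group needs n >= 4")
    return float(
        (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    )


def cohort_accuracy_table(logs) -> pd.DataFrame:
    """Per-agent learning/test means and forgetting for a list of logs."""
    rows = []
    for log in logs:
        prof = accuracy_profile(log)
        contrast = phase_contrast(prof)
        rows.append(
            {
                "agent_id": int(log["agent_id"].iloc[0]) if "agent_id" in log else -1,
                "condition": log["condition"].iloc[0] if "condition" in log else "",
                "learning_mean": prof.learning_mean,
                "test_mean": prof.test_mean,
                **contrast,
            }
        )
    return pd.DataFrame(rows)
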