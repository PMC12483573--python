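"""Feature-based and object-based reinforcement-learning models of the
value-based decision-making task, with global fitting and BIC comparison.

Four models are implemented.  Feature-based models learn a value in [0,1]
for each of the six feature levels (3 binary features) and choose between
two stimuli through a logistic on the weighted sum of feature-value
differences:

    logit P(left) = sum_f W_f * (V_f,left - V_f,right) + bias

Object-based models learn one value per stimulus:

    logit P(left) = W_o * (V_left - V_right) + bias

After feedback the chosen stimulus's value entries update asymmetrically,

    V <- V + alpha_reward * (1 - V)   if rewarded
    V <- V - alpha_unreward * V       if unrewarded,

and, in the decay variants, every entry NOT updated on that trial relaxes
toward the uninformative level 0.5 at rate d:  V <- V - d * (V - 0.5).

Models are fitted per agent by minimizing the sequential negative log
likelihood with differential evolution (global, seeded) and compared via
BIC = 2*NLL + k*ln(N) and its per-trial decomposition BIC_p whose sum
equals the global BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize, stats

from .task_design import FEATURE_LEVELS, N_FEATURES, N_STIMULI

FAMILIES = ("feature", "object")


@dataclass(frozen=True)
class ModelSpec:
    """Model family plus decay switch; ``k`` is the free-parameter count."""

    family: str
    decay: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")

    @property
    def k(self) -> int:
        # feature: 3 weights + bias + 2 learning rates (+ d)
        # object:  1 weight + bias + 2 learning rates (+ d)
        base = 6 if self.family == "feature" else 4
        return base + (1 if self.decay else 0)

    @property
    def name(self) -> str:
        return f"{self.family}{'+decay' if self.decay else ''}"

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.family == "feature":
            names = ["w_leg", "w_antennae", "w_mandible", "bias", "alpha_reward", "alpha_unreward"]
        else:
            names = ["w_object", "bias", "alpha_reward", "alpha_unreward"]
        if self.decay:
            names.append("decay")
        return tuple(names)


ALL_SPECS = (
    ModelSpec("object", False),
    ModelSpec("object", True),
    ModelSpec("feature", False),
    ModelSpec("feature", True),
)

#: fitting bounds; weights non-negative (the log-weight analysis requires
#: positivity), bias on the logit scale, rates and decay in the unit interval
DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "w_leg": (0.0, 20.0),
    "w_antennae": (0.0, 20.0),
    "w_mandible": (0.0, 20.0),
    "w_object": (0.0, 20.0),
    "bias": (-5.0, 5.0),
    "alpha_reward": (0.0, 1.0),
    "alpha_unreward": (0.0, 1.0),
    "decay": (0.0, 1.0),
}


@dataclass(frozen=True)
class ParamVector:
    """Parameters of one model; weight fields not used by the family are None."""

    w_leg: float | None = None
    w_antennae: float | None = None
    w_mandible: float | None = None
    w_object: float | None = None
    bias: float = 0.0
    alpha_reward: float = 0.0
    alpha_unreward: float = 0.0
    decay: float | None = None

    def to_array(self, spec: ModelSpec) -> np.ndarray:
        vals = [getattr(self, n) for n in spec.param_names]
        if any(v is None for v in vals):
            missing = [n for n, v in zip(spec.param_names, vals) if v is None]
            raise ValueError(f"params missing fields for {spec.name}: {missing}")
        return np.asarray(vals, dtype=np.float64)

    @staticmethod
    def from_array(x: Sequence[float], spec: ModelSpec) -> "ParamVector":
        return ParamVector(**dict(zip(spec.param_names, map(float, x))))


class ValueState:
    """Mutable learned values; one slot per feature level or per stimulus."""

    def __init__(self, family: str, init: float = 0.5):
        self.family = family
        if family == "feature":
            self.values = np.full((N_FEATURES, 2), init, dtype=np.float64)
        elif family == "object":
            self.values = np.full(N_STIMULI, init, dtype=np.float64)
        else:
            raise ValueError(f"unknown family {family!r}")

    def stimulus_value(self, stimulus_id: int) -> float:
        """Model-implied value of a stimulus (feature family: mean of its levels)."""
        if self.family == "object":
            return float(self.values[stimulus_id])
        levels = FEATURE_LEVELS[stimulus_id]
        return float(np.mean([self.values[f, levels[f]] for f in range(N_FEATURES)]))


def choice_probability(
    state: ValueState, left: int, right: int, params: ParamVector, family: str | None = None
) -> float:
    """P(choose left) under the family's logistic rule."""
    family = family or state.family
    if family == "feature":
        w = np.array([params.w_leg, params.w_antennae, params.w_mandible], dtype=np.float64)
        lv, rv = FEATURE_LEVELS[left], FEATURE_LEVELS[right]
        diff = np.array(
            [state.values[f, lv[f]] - state.values[f, rv[f]] for f in range(N_FEATURES)]
        )
        logit = float(w @ diff) + params.bias
    else:
        logit = params.w_object * (state.values[left] - state.values[right]) + params.bias
    return 1.0 / (1.0 + np.exp(-logit))


def update_chosen(
    state: ValueState,
    chosen: int,
    reward: int,
    alpha_reward: float,
    alpha_unreward: float,
) -> list[tuple]:
    """Asymmetric value update of the chosen stimulus; returns updated entries."""
    if reward not in (0, 1):
        raise ValueError("reward must be 0 or 1")
    if state.family == "object":
        entries = [(chosen,)]
    else:
        levels = FEATURE_LEVELS[chosen]
        entries = [(f, int(levels[f])) for f in range(N_FEATURES)]
    for e in entries:
        v = state.values[e]
        state.values[e] = v + alpha_reward * (1.0 - v) if reward else v - alpha_unreward * v
    return entries


def apply_decay(state: ValueState, updated_entries: Iterable[tuple], d: float) -> None:
    """Relax every entry not updated this trial toward 0.5: V <- V - d*(V-0.5)."""
    updated = set(updated_entries)
    it = np.ndindex(state.values.shape)
    for e in it:
        key = e if state.family == "feature" else (e[0],)
        if key not in updated:
            state.values[e] -= d * (state.values[e] - 0.5)


# ---------------------------------------------------------------------------
# fast sequential likelihood (replayed trial by trial)

@njit(cache=True)
def _ll_trace_feature(left_levels, right_levels, choices, rewards,
                      w, bias, ar, au, d, use_decay):  # pragma: no cover - jitted
    n = choices.shape[0]
    V = np.full((3, 2), 0.5)
    ll = np.empty(n)
    for t in range(n):
        logit = bias
        for f in range(3):
            logit += w[f] * (V[f, left_levels[t, f]] - V[f, right_levels[t, f]])
        p_left = 1.0 / (1.0 + np.exp(-logit))
        p = p_left if choices[t] == 0 else 1.0 - p_left
        if p < 1e-300:
            p = 1e-300
        ll[t] = np.log(p)
        lv = left_levels[t] if choices[t] == 0 else right_levels[t]
        for f in range(3):
            v = V[f, lv[f]]
            V[f, lv[f]] = v + ar * (1.0 - v) if rewards[t] == 1 else v - au * v
        if use_decay:
            for f in range(3):
                other = 1 - lv[f]
                V[f, other] -= d * (V[f, other] - 0.5)
    return ll


@njit(cache=True)
def _ll_trace_object(lefts, rights, choices, rewards,
                     wo, bias, ar, au, d, use_decay):  # pragma: no cover - jitted
    n = choices.shape[0]
    V = np.full(8, 0.5)
    ll = np.empty(n)
    for t in range(n):
        logit = wo * (V[lefts[t]] - V[rights[t]]) + bias
        p_left = 1.0 / (1.0 + np.exp(-logit))
        p = p_left if choices[t] == 0 else 1.0 - p_left
        if p < 1e-300:
            p = 1e-300
        ll[t] = np.log(p)
        c = lefts[t] if choices[t] == 0 else rights[t]
        v = V[c]
        V[c] = v + ar * (1.0 - v) if rewards[t] == 1 else v - au * v
        if use_decay:
            for s in range(8):
                if s != c:
                    V[s] -= d * (V[s] - 0.5)
    return ll


def _log_arrays(log: pd.DataFrame):
    if log["response"].isna().any():
        raise ValueError("log has missing responses")
    lefts = log["left_stimulus_id"].to_numpy(dtype=np.int64)
    rights = log["right_stimulus_id"].to_numpy(dtype=np.int64)
    choices = log["response"].to_numpy(dtype=np.int64)  # 0=left, 1=right
    rewards = log["reward"].to_numpy(dtype=np.int64)
    return lefts, rights, choices, rewards


def negative_log_likelihood(
    log: pd.DataFrame, spec: ModelSpec, params: ParamVector | Sequence[float]
) -> tuple[float, np.ndarray]:
    """Sequential NLL of a value-task response log; returns (NLL, LL trace).

    The log is replayed trial by trial: the choice probability is scored,
    then the chosen stimulus is updated and (in decay variants) the
    remaining entries decay.  Values start at 0.5.
    """
    if isinstance(params, ParamVector):
        x = params.to_array(spec)
    else:
        x = np.asarray(params, dtype=np.float64)
    lefts, rights, choices, rewards = _log_arrays(log)
    if spec.family == "feature":
        w = x[:3]
        bias, ar, au = x[3], x[4], x[5]
        d = x[6] if spec.decay else 0.0
        ll = _ll_trace_feature(
            FEATURE_LEVELS[lefts], FEATURE_LEVELS[rights], choices, rewards,
            w, bias, ar, au, d, spec.decay,
        )
    else:
        wo, bias, ar, au = x[0], x[1], x[2], x[3]
        d = x[4] if spec.decay else 0.0
        ll = _ll_trace_object(lefts, rights, choices, rewards, wo, bias, ar, au, d, spec.decay)
    return float(-np.sum(ll)), ll


def bic(nll: float, k: int, n_trials: int) -> float:
    """BIC = 2*NLL + k*ln(N) (natural log)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return 2.0 * nll + k * np.log(n_trials)


def bic_per_trial(ll_trace: np.ndarray, k: int, n_trials: int) -> np.ndarray:
    """Per-trial decomposition BIC_p(t) = -2*LL(t) + k*ln(N)/N.

    The penalty is spread uniformly over trials so the cumulative sum over
    all trials equals the global BIC exactly.
    """
    ll_trace = np.asarray(ll_trace, dtype=np.float64)
    if ll_trace.shape[0] != n_trials:
        raise ValueError("trace length must equal n_trials")
    return -2.0 * ll_trace + k * np.log(n_trials) / n_trials


def running_average(trace: Sequence[float], window: int = 20) -> np.ndarray:
    """Centered moving mean with edge truncation (mean over available points)."""
    trace = np.asarray(trace, dtype=np.float64)
    n = trace.shape[0]
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds trace length {n}")
    half_lo = (window - 1) // 2
    half_hi = window // 2
    out = np.empty(n)
    for t in range(n):
        lo = max(0, t - half_lo)
        hi = min(n, t + half_hi + 1)
        out[t] = trace[lo:hi].mean()
    return out


def bic_difference_slope(bic_p_object: Sequence[float], bic_p_feature: Sequence[float]) -> float:
    """OLS slope of BIC_p(object) - BIC_p(feature) against the 0-based trial index.

    A negative slope means the object-based account gains on the
    feature-based one over the course of the session.
    """
    a = np.asarray(bic_p_object, dtype=np.float64)
    b = np.asarray(bic_p_feature, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("traces must have the same length")
    t = np.arange(a.shape[0], dtype=np.float64)
    return float(np.polyfit(t, a - b, 1)[0])


@dataclass
class OptimizerConfig:
    popsize: int = 15  # scipy multiplier: population = popsize * n_params
    tol: float = 1e-7
    maxiter: int = 1000
    polish: bool = True


@dataclass
class FitResult:
    spec: ModelSpec
    params: ParamVector
    nll: float
    ll_trace: np.ndarray
    bic: float
    bic_p: np.ndarray
    n_trials: int
    converged: bool
    n_iterations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "k": self.spec.k,
            "params": dict(zip(self.spec.param_names, self.params.to_array(self.spec).tolist())),
            "nll": self.nll,
            "bic": self.bic,
            "n_trials": self.n_trials,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }

    def traces_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": np.arange(1, self.n_trials + 1), "ll": self.ll_trace, "bic_p": self.bic_p}
        )


def fit(
    log: pd.DataFrame,
    spec: ModelSpec,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    optimizer_config: OptimizerConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit one model to one agent's value-task log by differential evolution.

    The global optimizer evolves a population of candidate parameter
    vectors within the bounds; the run is seeded and reproducible.
    Non-convergence is reported through ``converged``, never silently.
    """
    if len(log) < 1:
        raise ValueError("empty log")
    cfg = optimizer_config or OptimizerConfig()
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    box = [bnds[name] for name in spec.param_names]
    lefts, rights, choices, rewards = _log_arrays(log)
    n = len(log)
    if spec.family == "feature":
        ll_lev, rr_lev = FEATURE_LEVELS[lefts], FEATURE_LEVELS[rights]

        def objective(x):
            d = x[6] if spec.decay else 0.0
            tr = _ll_trace_feature(ll_lev, rr_lev, choices, rewards,
                                   x[:3], x[3], x[4], x[5], d, spec.decay)
            return -np.sum(tr)
    else:

        def objective(x):
            d = x[4] if spec.decay else 0.0
            tr = _ll_trace_object(lefts, rights, choices, rewards,
                                  x[0], x[1], x[2], x[3], d, spec.decay)
            return -np.sum(tr)

    res = optimize.differential_evolution(
        objective,
        bounds=box,
        seed=seed,
        popsize=cfg.popsize,
        tol=cfg.tol,
        maxiter=cfg.maxiter,
        polish=cfg.polish,
    )
    params = ParamVector.from_array(res.x, spec)
    nll, ll_trace = negative_log_likelihood(log, spec, params)
    b = bic(nll, spec.k, n)
    return FitResult(
        spec=spec,
        params=params,
        nll=nll,
        ll_trace=ll_trace,
        bic=b,
        bic_p=bic_per_trial(ll_trace, spec.k, n),
        n_trials=n,
        converged=bool(res.success),
        n_iterations=int(res.nit),
        seed=seed,
    )


def log_feature_weights(result: FitResult, floor: float = 1e-6) -> tuple[float, float, float]:
    """Natural log of the three feature weights, floored at ``floor``.

    The log transform normalizes the weight distribution for the
    attentional-weight analysis; flooring keeps zero weights finite.
    """
    if result.spec.family != "feature":
        raise ValueError("log weights are defined for the feature family only")
    p = result.params
    return tuple(float(np.log(max(w, floor))) for w in (p.w_leg, p.w_antennae, p.w_mandible))


def compare_models(
    fits: Mapping[str, Mapping[str, FitResult]],
    contrasts: Sequence[tuple[str, str]] = (("feature+decay", "object+decay"),),
) -> dict:
    """Model comparison across agents.

    ``fits`` maps agent id -> {model name -> FitResult}; every agent must
    carry the same model set.  Returns per-model mean +/- SEM of BIC and
    NLL, per-agent BIC differences for the stated contrasts, and the
    paired signed-rank test on each contrast.
    """
    agents = sorted(fits)
    if not agents:
        raise ValueError("no fits supplied")
    model_sets = {tuple(sorted(fits[a])) for a in agents}
    if len(model_sets) != 1:
        raise ValueError(f"agents carry mismatched model sets: {model_sets}")
    models = list(model_sets.pop())
    table = []
    for m in models:
        bics = np.array([fits[a][m].bic for a in agents])
        nlls = np.array([fits[a][m].nll for a in agents])
        table.append(
            {
                "model": m,
                "k": fits[agents[0]][m].spec.k,
                "bic_mean": bics.mean(),
                "bic_sem": stats.sem(bics) if len(agents) > 1 else 0.0,
                "nll_mean": nlls.mean(),
                "nll_sem": stats.sem(nlls) if len(agents) > 1 else 0.0,
            }
        )
    comparison: dict = {"table": pd.DataFrame(table), "contrasts": {}}
    for m1, m2 in contrasts:
        if m1 not in models or m2 not in models:
            continue
        diffs = np.array([fits[a][m1].bic - fits[a][m2].bic for a in agents])
        entry: dict = {"bic_diff_mean": float(diffs.mean()), "bic_diffs": diffs}
        if len(agents) > 1 and np.any(diffs != 0):
            w = stats.wilcoxon(diffs)
            entry["signed_rank_stat"] = float(w.statistic)
            entry["signed_rank_p"] = float(w.pvalue)
        comparison["contrasts"][f"{m1} - {m2}"] = entry
    best = min(table, key=lambda row: row["bic_mean"])
    comparison["best_model"] = best["model"]
    return comparison


def rank_sum_between_groups(values_a: Sequence[float], values_b: Sequence[float]) -> dict:
    """Two-sample rank-sum (Mann-Whitney U) contrast between agent groups."""
    u = stats.mannwhitneyu(values_a, values_b, alternative="two-sided")
    return {"U": float(u.statistic), "p": float(u.pvalue)}
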