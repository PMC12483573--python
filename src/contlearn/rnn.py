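"""Recurrent-network fits of choice logs and representational geometry.

A simple Elman recurrent network (one recurrent tanh layer, dense softmax
output) is trained to predict an agent's responses on the learning phase,
one network per agent.  Each trial is a 10-timestep sequence with two
input streams: a 5-channel stimulus code (3 feature bits, zero-padded)
and a 3-channel one-hot task context.  Depending on the presentation
order, the first five timesteps carry only the stimulus or only the
context; both streams are active on the last five.  Hidden state is
reset between trials, the loss is categorical cross-entropy on the final
timestep's output, optimization is Adam with early stopping on
validation loss.

From the trained network the hidden activation at the final timestep is
probed for each of the 24 stimulus-by-task combinations, yielding two
geometry scores:

* Task Separation — mean Euclidean distance between one stimulus's
  representations across the three task contexts, averaged over stimuli;
* Task Specialization — mean Spearman correlation between each task's
  8x8 representational dissimilarity matrix and the binary ground-truth
  matrix defined by the task-relevant feature.

Finally, ordinary-least-squares regressions relate these scores (mean-
centered) and the labeling condition to learning accuracy, with and
without interaction terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from . import task_design
from .task_design import N_STIMULI, N_TASKS, TaskRule


@dataclass(frozen=True)
class NetConfig:
    hidden_units: int = 48
    timesteps_per_trial: int = 10
    stimulus_input_width: int = 5
    context_input_width: int = 3
    output_width: int = 2
    learning_rate: float = 1e-4
    batch_size: int = 72
    early_stop_patience: int = 3
    max_epochs: int = 10000
    reset_state_between_trials: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("hidden_units", "timesteps_per_trial", "stimulus_input_width",
                     "context_input_width", "output_width", "batch_size", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def input_width(self) -> int:
        return self.stimulus_input_width + self.context_input_width


#: reduced configuration for quick runs: fewer units, a faster learning
#: rate and a capped epoch budget; the faster rate makes the validation
#: loss noisier epoch to epoch, so the patience scales up accordingly
SMALL_NET = NetConfig(hidden_units=8, learning_rate=1e-3, max_epochs=2000,
                      early_stop_patience=150)


@dataclass
class EncodedDataset:
    """Per-trial input tensors (n, T, channels), response labels, and split."""

    X: np.ndarray
    y: np.ndarray
    train_mask: np.ndarray
    order_condition: str

    @property
    def n_train(self) -> int:
        return int(self.train_mask.sum())

    @property
    def n_val(self) -> int:
        return int((~self.train_mask).sum())


def encode_trial_input(
    stimulus_id: int, task_id: int, order_condition: str, config: NetConfig
) -> np.ndarray:
    """(timesteps, stimulus_width + context_width) input for one trial."""
    T = config.timesteps_per_trial
    X = np.zeros((T, config.input_width))
    stim = np.zeros(config.stimulus_input_width)
    stim[: task_design.N_FEATURES] = task_design.FEATURE_LEVELS[stimulus_id]
    ctx = np.zeros(config.context_input_width)
    ctx[task_id] = 1.0
    first = T // 2
    if order_condition == "stimulus_first":
        X[:first, : config.stimulus_input_width] = stim
    elif order_condition == "context_first":
        X[:first, config.stimulus_input_width:] = ctx
    else:
        raise ValueError(f"unknown order_condition {order_condition!r}")
    X[first:, : config.stimulus_input_width] = stim
    X[first:, config.stimulus_input_width:] = ctx
    return X


def encode_trials(
    log: pd.DataFrame, order_condition: str, config: NetConfig | None = None
) -> EncodedDataset:
    """Encode a learning-phase log; labels are the log's responses.

    The first 36 trials of each 48-trial block go to the training split,
    the last 12 to validation.
    """
    config = config or NetConfig()
    learning = log[log["phase"] == "learning"].reset_index(drop=True)
    if len(learning) == 0:
        raise ValueError("log has no learning-phase trials")
    n = len(learning)
    X = np.stack(
        [
            encode_trial_input(int(r.stimulus_id), int(r.task_id), order_condition, config)
            for r in learning.itertuples()
        ]
    )
    y = learning["response"].to_numpy(dtype=np.int64)
    train_mask = np.zeros(n, dtype=bool)
    for _, idx in learning.groupby("block").groups.items():
        idx = np.asarray(idx)
        per_block = len(idx)
        n_train = int(round(per_block * 36 / 48))
        train_mask[idx[:n_train]] = True
    return EncodedDataset(X, y, train_mask, order_condition)


class ElmanNetwork:
    """Elman recurrent layer + dense softmax output, trained by Adam/BPTT."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        D, H, O = config.input_width, config.hidden_units, config.output_width
        self.Wx = _glorot(rng, (D, H))
        self.Wh = _glorot(rng, (H, H))
        self.bh = np.zeros(H)
        self.Wo = _glorot(rng, (H, O))
        self.bo = np.zeros(O)
        self._adam = {k: [np.zeros_like(v), np.zeros_like(v)] for k, v in self._params().items()}
        self._adam_t = 0

    def _params(self) -> dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "bh": self.bh, "Wo": self.Wo, "bo": self.bo}

    def hidden_states(self, X: np.ndarray) -> np.ndarray:
        """(n, T, H) hidden activations; state is zero at each trial start."""
        n, T, _ = X.shape
        H = self.config.hidden_units
        hs = np.empty((n, T, H))
        h = np.zeros((n, H))
        for t in range(T):
            h = np.tanh(X[:, t, :] @ self.Wx + h @ self.Wh + self.bh)
            hs[:, t, :] = h
        return hs

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hs = self.hidden_states(X)
        logits = hs[:, -1, :] @ self.Wo + self.bo
        logits = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        return hs, probs

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        _, probs = self.forward(X)
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        _, probs = self.forward(X)
        return probs.argmax(axis=1)

    def _gradients(self, X: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
        n, T, _ = X.shape
        hs, probs = self.forward(X)
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        g = {k: np.zeros_like(v) for k, v in self._params().items()}
        g["Wo"] = hs[:, -1, :].T @ dlogits
        g["bo"] = dlogits.sum(axis=0)
        dh = dlogits @ self.Wo.T
        for t in range(T - 1, -1, -1):
            da = dh * (1.0 - hs[:, t, :] ** 2)
            g["Wx"] += X[:, t, :].T @ da
            prev = hs[:, t - 1, :] if t > 0 else np.zeros_like(hs[:, 0, :])
            g["Wh"] += prev.T @ da
            g["bh"] += da.sum(axis=0)
            dh = da @ self.Wh.T
        return g

    def adam_step(self, grads: dict[str, np.ndarray],
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        lr = self.config.learning_rate
        for k, p in self._params().items():
            m, v = self._adam[k]
            m[:] = beta1 * m + (1 - beta1) * grads[k]
            v[:] = beta2 * v + (1 - beta2) * grads[k] ** 2
            mhat = m / (1 - beta1 ** self._adam_t)
            vhat = v / (1 - beta2 ** self._adam_t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._params().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in self._params().items():
            v[:] = weights[k]


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class TrainResult:
    network: ElmanNetwork
    fit_accuracy: float  # validation response-prediction accuracy
    epochs_run: int
    best_val_loss: float
    stopped_early: bool


def train_network(dataset: EncodedDataset, config: NetConfig | None = None) -> TrainResult:
    """Train an Elman network on a dataset; early stop on validation loss.

    Raises on divergent (NaN) loss.  Re-running with the same config and
    seed reproduces the weights bit for bit.
    """
    config = config or NetConfig()
    if len(dataset.y) == 0:
        raise ValueError("empty dataset")
    net = ElmanNetwork(config)
    rng = np.random.default_rng(config.seed + 1)
    Xtr, ytr = dataset.X[dataset.train_mask], dataset.y[dataset.train_mask]
    Xva, yva = dataset.X[~dataset.train_mask], dataset.y[~dataset.train_mask]
    if len(yva) == 0:  # degenerate split: validate on train
        Xva, yva = Xtr, ytr
    best_loss = np.inf
    best_weights = net.get_weights()
    patience_left = config.early_stop_patience
    epochs = 0
    stopped = False
    n = len(ytr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            grads = net._gradients(Xtr[idx], ytr[idx])
            net.adam_step(grads)
        val_loss = net.loss(Xva, yva)
        epochs = epoch + 1
        if not np.isfinite(val_loss):
            raise FloatingPointError(
                f"divergent validation loss at epoch {epochs} "
                f"(lr={config.learning_rate}, hidden={config.hidden_units})"
            )
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_weights = net.get_weights()
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                stopped = True
                break
    net.set_weights(best_weights)
    acc = float(np.mean(net.predict(Xva) == yva))
    return TrainResult(net, acc, epochs, float(best_loss), stopped)


def probe_representations(
    network: ElmanNetwork, config: NetConfig | None = None,
    order_condition: str = "stimulus_first",
) -> np.ndarray:
    """(8, 3, hidden) final-timestep hidden activations per stimulus x task."""
    config = config or network.config
    reps = np.empty((N_STIMULI, N_TASKS, config.hidden_units))
    for s in range(N_STIMULI):
        for t in range(N_TASKS):
            X = encode_trial_input(s, t, order_condition, config)[None]
            reps[s, t] = network.hidden_states(X)[0, -1, :]
    return reps


def task_separation(reps: np.ndarray) -> float:
    """Mean over stimuli of the mean pairwise distance across task contexts."""
    reps = _check_reps(reps)
    per_insect = [np.mean(pdist(reps[s])) for s in range(N_STIMULI)]
    return float(np.mean(per_insect))


def ground_truth_rdm(task_rule: TaskRule) -> np.ndarray:
    """8x8 binary dissimilarity: 1 iff the stimuli differ on the relevant feature."""
    levels = task_design.FEATURE_LEVELS[:, task_rule.relevant_feature]
    return (levels[:, None] != levels[None, :]).astype(np.float64)


def task_specialization(
    reps: np.ndarray, task_rules: Sequence[TaskRule] | None = None
) -> float:
    """Mean Spearman correlation of per-task RDMs with their ground truths.

    A task whose empirical RDM has zero variance is reported as missing
    with a warning and dropped from the average.
    """
    reps = _check_reps(reps)
    rdms = [squareform(pdist(reps[:, t, :])) for t in range(N_TASKS)]
    return specialization_from_rdms(rdms, task_rules)


def specialization_from_rdms(
    rdms: Sequence[np.ndarray], task_rules: Sequence[TaskRule] | None = None
) -> float:
    """Spearman(RDM, ground truth) per task on the strict lower triangles,
    averaged over tasks; see :func:`task_specialization`."""
    rules = list(task_rules) if task_rules is not None else task_design.default_task_rules()
    if len(rdms) != len(rules):
        raise ValueError("need one RDM per task rule")
    tri = np.tril_indices(N_STIMULI, k=-1)
    scores = []
    for t, (rdm, rule) in enumerate(zip(rdms, rules)):
        gt = ground_truth_rdm(rule)
        if np.std(rdm[tri]) == 0:
            warnings.warn(f"task {t}: zero-variance RDM, specialization undefined",
                          stacklevel=2)
            continue
        rho = sps.spearmanr(rdm[tri], gt[tri]).statistic
        scores.append(float(rho))
    return float(np.mean(scores)) if scores else float("nan")


def _check_reps(reps: np.ndarray) -> np.ndarray:
    reps = np.asarray(reps, dtype=np.float64)
    if reps.shape[:2] != (N_STIMULI, N_TASKS):
        raise ValueError(f"expected representations of shape (8, 3, H), got {reps.shape}")
    if not np.all(np.isfinite(reps)):
        raise ValueError("representations contain non-finite entries")
    return reps


def geometry_scores(
    network: ElmanNetwork, fit_accuracy: float,
    config: NetConfig | None = None, order_condition: str = "stimulus_first",
    task_rules: Sequence[TaskRule] | None = None,
) -> dict:
    reps = probe_representations(network, config, order_condition)
    return {
        "fit_accuracy": fit_accuracy,
        "task_separation": task_separation(reps),
        "task_specialization": task_specialization(reps, task_rules),
    }


def fit_geometry_regressions(
    scores: pd.DataFrame,
    accuracy_col: str = "accuracy",
    separation_col: str = "task_separation",
    specialization_col: str = "task_specialization",
    labeling_col: str = "labeling",
) -> dict:
    """OLS of accuracy on geometry scores and labeling condition.

    Model 1 has main effects only; Model 2 adds the two score-by-labeling
    interactions.  Continuous predictors are mean-centered before
    fitting.  Returns both fitted models, coefficient tables, R^2, the
    increment in R^2, and the nested-model F-test.
    """
    df = scores.copy()
    per_cond = df.groupby(labeling_col).size()
    if (per_cond < 10).any() if len(per_cond) > 1 else len(df) < 10:
        raise ValueError("need >= 10 agents per condition")
    sep = df[separation_col] - df[separation_col].mean()
    spec = df[specialization_col] - df[specialization_col].mean()
    lab = df[labeling_col].astype(float)
    X1 = pd.DataFrame({"task_separation": sep, "task_specialization": spec, "labeling": lab})
    X2 = X1.assign(
        **{"task_separation:labeling": sep * lab, "task_specialization:labeling": spec * lab}
    )
    y = df[accuracy_col].astype(float)
    for name, X in (("Model 1", X1), ("Model 2", X2)):
        exog = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(exog.to_numpy())
        if rank < exog.shape[1]:
            bad = _collinear_columns(exog)
            raise ValueError(f"{name} design matrix is rank deficient; collinear columns: {bad}")
    m1 = sm.OLS(y, sm.add_constant(X1, has_constant="add")).fit()
    m2 = sm.OLS(y, sm.add_constant(X2, has_constant="add")).fit()
    f_stat, f_p, df_diff = m2.compare_f_test(m1)
    return {
        "model1": m1,
        "model2": m2,
        "coefficients_model1": m1.params.to_dict(),
        "coefficients_model2": m2.params.to_dict(),
        "r2_model1": float(m1.rsquared),
        "r2_model2": float(m2.rsquared),
        "delta_r2": float(m2.rsquared - m1.rsquared),
        "f_stat": float(f_stat),
        "f_p": float(f_p),
        "df_diff": float(df_diff),
    }


def _collinear_columns(exog: pd.DataFrame) -> list[str]:
    _, r = np.linalg.qr(exog.to_numpy())
    diag = np.abs(np.diag(r))
    tol = diag.max() * 1e-10
    return [c for c, d in zip(exog.columns, diag) if d < tol]


def architecture_sweep(
    dataset: EncodedDataset,
    hidden_grid: Sequence[int] = (8, 24, 48),
    timestep_grid: Sequence[int] = (2, 10),
    base_config: NetConfig | None = None,
) -> pd.DataFrame:
    """Score a config grid by validation loss; returns one row per config."""
    base = base_config or NetConfig()
    rows = []
    for h in hidden_grid:
        for T in timestep_grid:
            cfg = replace(base, hidden_units=h, timesteps_per_trial=T)
            ds = dataset
            if T != dataset.X.shape[1]:
                # re-encode at the new trial length is the caller's job;
                # subsample timesteps keeping the final ones as a cheap proxy
                ds = EncodedDataset(dataset.X[:, -T:, :], dataset.y,
                                    dataset.train_mask, dataset.order_condition)
            res = train_network(ds, cfg)
            rows.append({"hidden_units": h, "timesteps": T,
                         "val_loss": res.best_val_loss, "fit_accuracy": res.fit_accuracy})
    return pd.DataFrame(rows)
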