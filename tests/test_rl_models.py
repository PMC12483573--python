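"""RL model equations, sequential likelihood, fitting, and BIC machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contlearn import agents, rl_models as rl, task_design as td
from conftest import make_tiny_log

FEATURE_DECAY = rl.ModelSpec("feature", True)
OBJECT_DECAY = rl.ModelSpec("object", True)


# ---------------------------------------------------------------------------
# independent brute-force replay oracle (pure python, no shared code paths)

def oracle_nll(log, spec, params):
    """Spreadsheet-style replay of the model equations."""
    levels = [((i >> 0) & 1, (i >> 1) & 1, (i >> 2) & 1) for i in range(8)]
    if spec.family == "feature":
        V = {(f, l): 0.5 for f in range(3) for l in range(2)}
        weights = [params.w_leg, params.w_antennae, params.w_mandible]
    else:
        V = {s: 0.5 for s in range(8)}
    total = 0.0
    for row in log.itertuples():
        left, right = row.left_stimulus_id, row.right_stimulus_id
        if spec.family == "feature":
            logit = params.bias + sum(
                weights[f] * (V[(f, levels[left][f])] - V[(f, levels[right][f])])
                for f in range(3)
            )
        else:
            logit = params.w_object * (V[left] - V[right]) + params.bias
        p_left = 1.0 / (1.0 + math.exp(-logit))
        p = p_left if row.response == 0 else 1.0 - p_left
        total -= math.log(p)
        chosen = left if row.response == 0 else right
        if spec.family == "feature":
            touched = [(f, levels[chosen][f]) for f in range(3)]
        else:
            touched = [chosen]
        for key in touched:
            v = V[key]
            V[key] = v + params.alpha_reward * (1 - v) if row.reward else \
                v - params.alpha_unreward * v
        if spec.decay:
            for key in V:
                if key not in touched:
                    V[key] -= params.decay * (V[key] - 0.5)
    return total


# ---------------------------------------------------------------------------


def test_parameter_counts_match_model_structure():
    assert rl.ModelSpec("feature", False).k == 6
    assert rl.ModelSpec("feature", True).k == 7
    assert rl.ModelSpec("object", False).k == 4
    assert rl.ModelSpec("object", True).k == 5


class TestChoiceProbability:
    def test_equal_values_zero_bias_gives_half(self):
        state = rl.ValueState("object")
        p = rl.choice_probability(state, 0, 5, rl.ParamVector(w_object=3.0))
        assert p == pytest.approx(0.5)

    def test_object_logistic_direct_evaluation(self):
        state = rl.ValueState("object")
        state.values[0], state.values[1] = 0.65, 0.35
        p = rl.choice_probability(state, 0, 1, rl.ParamVector(w_object=5.0, bias=0.0))
        assert p == pytest.approx(1 / (1 + math.exp(-1.5)), abs=1e-12)  # 0.81757...

    def test_swapping_sides_is_antisymmetric(self):
        state = rl.ValueState("feature")
        state.values[:] = np.random.default_rng(0).uniform(0.2, 0.8, size=(3, 2))
        pv = rl.ParamVector(w_leg=1.0, w_antennae=2.0, w_mandible=0.5, bias=0.0)
        p = rl.choice_probability(state, 2, 6, pv)
        q = rl.choice_probability(state, 6, 2, pv)
        assert p == pytest.approx(1.0 - q, abs=1e-12)


class TestUpdateRules:
    def test_hand_worked_updates(self):
        state = rl.ValueState("object")
        rl.update_chosen(state, 3, reward=1, alpha_reward=0.2, alpha_unreward=0.0)
        assert state.values[3] == pytest.approx(0.6)
        state.values[3] = 0.5
        rl.update_chosen(state, 3, reward=0, alpha_reward=0.0, alpha_unreward=0.2)
        assert state.values[3] == pytest.approx(0.4)

    def test_fixed_points(self):
        state = rl.ValueState("object")
        state.values[0] = 1.0
        rl.update_chosen(state, 0, 1, 0.7, 0.7)
        assert state.values[0] == pytest.approx(1.0)
        state.values[1] = 0.37
        rl.update_chosen(state, 1, 1, 0.0, 0.0)
        assert state.values[1] == pytest.approx(0.37)

    def test_feature_update_touches_only_chosen_levels(self):
        state = rl.ValueState("feature")
        entries = rl.update_chosen(state, 7, 1, 0.5, 0.5)  # all-thin/pincer stimulus
        assert set(entries) == {(0, 1), (1, 1), (2, 1)}
        assert np.all(state.values[:, 1] == 0.75)
        assert np.all(state.values[:, 0] == 0.5)

    def test_decay_moves_untouched_entries_toward_half(self):
        state = rl.ValueState("object")
        state.values[:] = 0.9
        rl.apply_decay(state, [(0,)], d=0.1)
        assert state.values[0] == pytest.approx(0.9)
        assert np.all(state.values[1:] == pytest.approx(0.86))  # 0.9 - 0.1*0.4
        rl.apply_decay(state, [], d=0.0)
        assert state.values[0] == pytest.approx(0.9)  # d=0 is the identity
        state.values[:] = 0.5
        rl.apply_decay(state, [], d=0.73)
        assert np.all(state.values == 0.5)  # attractor fixed point

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_values_stay_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        state = rl.ValueState("feature")
        for _ in range(50):
            chosen = int(rng.integers(8))
            entries = rl.update_chosen(state, chosen, int(rng.integers(2)),
                                       rng.uniform(0, 1), rng.uniform(0, 1))
            rl.apply_decay(state, entries, rng.uniform(0, 1))
            assert np.all((state.values >= 0) & (state.values <= 1))


class TestLikelihood:
    def test_uniform_model_gives_n_log_two(self, value_log):
        pv = rl.ParamVector(w_leg=0, w_antennae=0, w_mandible=0, bias=0,
                            alpha_reward=0.3, alpha_unreward=0.3, decay=0.1)
        nll, trace = rl.negative_log_likelihood(value_log, FEATURE_DECAY, pv)
        assert nll == pytest.approx(336 * math.log(2), rel=1e-12)
        assert trace.shape == (336,)

    @pytest.mark.parametrize("spec", [rl.ModelSpec("feature", False), FEATURE_DECAY,
                                      rl.ModelSpec("object", False), OBJECT_DECAY])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_on_short_logs(self, spec, seed):
        log = make_tiny_log(n=10, seed=seed)
        if spec.family == "feature":
            pv = rl.ParamVector(w_leg=1.3, w_antennae=4.0, w_mandible=0.2, bias=-0.4,
                                alpha_reward=0.45, alpha_unreward=0.2, decay=0.15)
        else:
            pv = rl.ParamVector(w_object=5.1, bias=0.3,
                                alpha_reward=0.45, alpha_unreward=0.2, decay=0.15)
        nll, trace = rl.negative_log_likelihood(log, spec, pv)
        assert nll == pytest.approx(oracle_nll(log, spec, pv), abs=1e-12)
        assert -trace.sum() == pytest.approx(nll, rel=1e-12)

    def test_missing_responses_rejected(self, tiny_log):
        bad = tiny_log.copy()
        bad.loc[3, "response"] = np.nan
        pv = rl.ParamVector(w_object=1.0, alpha_reward=0.1, alpha_unreward=0.1)
        with pytest.raises(ValueError, match="missing"):
            rl.negative_log_likelihood(bad, rl.ModelSpec("object"), pv)


class TestBic:
    #: (NLL mean, k, printed BIC mean) from the group-level comparison table
    TABLE_ROWS = [
        (219.197, 4, 461.649), (213.129, 5, 455.327),
        (208.402, 6, 451.687), (204.562, 7, 449.820),
        (212.035, 4, 447.328), (204.707, 5, 438.488),
        (197.190, 6, 429.269), (192.199, 7, 425.101),
    ]

    def test_bic_formula_arithmetic(self):
        assert rl.bic(204.562, 7, 336) == pytest.approx(449.842, abs=5e-3)
        assert rl.bic(219.197, 4, 336) == pytest.approx(461.662, abs=5e-3)
        assert rl.bic(100.0, 0, 336) == 200.0  # no penalty when k=0

    @pytest.mark.parametrize("nll,k,expected", TABLE_ROWS)
    def test_natural_log_penalty_reproduces_all_printed_rows(self, nll, k, expected):
        # confirms the 2*NLL + k*ln(N) convention at N=336 on rounded means
        assert rl.bic(nll, k, 336) == pytest.approx(expected, abs=0.05)

    def test_per_trial_decomposition_conserves_bic(self, value_log, feature_decay_agent):
        nll, trace = rl.negative_log_likelihood(value_log, FEATURE_DECAY,
                                                feature_decay_agent.params)
        bp = rl.bic_per_trial(trace, FEATURE_DECAY.k, len(value_log))
        total = rl.bic(nll, FEATURE_DECAY.k, len(value_log))
        assert bp.sum() == pytest.approx(total, rel=1e-9)
        # the penalty share is constant over trials
        penalty = bp + 2.0 * trace
        assert np.allclose(penalty, FEATURE_DECAY.k * math.log(336) / 336)

    def test_single_trial_chance_decomposition(self):
        bp = rl.bic_per_trial(np.array([math.log(0.5)]), k=1, n_trials=1)
        assert bp[0] == pytest.approx(2 * math.log(2), abs=1e-12)  # ln(1) penalty = 0


class TestRunningAverage:
    def test_constant_and_identity_windows(self):
        x = np.full(30, 3.7)
        assert np.allclose(rl.running_average(x, 20), 3.7)
        y = np.arange(30.0)
        assert np.allclose(rl.running_average(y, 1), y)

    def test_linear_ramp_interior_unchanged(self):
        y = np.arange(100.0)
        sm = rl.running_average(y, 21)  # odd window: exactly centered
        assert np.allclose(sm[10:-10], y[10:-10])

    def test_window_larger_than_trace_errors(self):
        with pytest.raises(ValueError):
            rl.running_average(np.arange(5.0), 6)


class TestSlope:
    def test_identical_traces_give_zero(self):
        tr = np.random.default_rng(0).normal(size=100)
        assert rl.bic_difference_slope(tr, tr) == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_difference(self):
        n = 336
        base = np.random.default_rng(1).normal(size=n)
        diff = -0.001 * np.arange(n)
        assert rl.bic_difference_slope(base + diff, base) == pytest.approx(-0.001)


class TestFitting:
    def test_fit_dominates_generating_parameters(self, value_log, feature_decay_agent):
        fr = rl.fit(value_log, FEATURE_DECAY, seed=5)
        gen_nll, _ = rl.negative_log_likelihood(value_log, FEATURE_DECAY,
                                                feature_decay_agent.params)
        assert fr.nll <= gen_nll + 1e-3
        assert fr.converged
        # the generating weight structure is recovered
        assert fr.params.w_antennae > fr.params.w_leg
        assert fr.params.w_antennae > fr.params.w_mandible

    def test_fit_is_reproducible(self, value_log):
        a = rl.fit(value_log, OBJECT_DECAY, seed=9)
        b = rl.fit(value_log, OBJECT_DECAY, seed=9)
        assert a.nll == b.nll
        assert np.array_equal(a.params.to_array(OBJECT_DECAY),
                              b.params.to_array(OBJECT_DECAY))

    def test_random_choices_fit_near_chance(self, value_schedule):
        rng = np.random.default_rng(3)
        log = value_schedule.to_frame().rename(columns={})
        log["response"] = rng.integers(2, size=len(log))
        log["reward"] = rng.integers(2, size=len(log))
        fr = rl.fit(log, rl.ModelSpec("object"), seed=4)
        chance = len(log) * math.log(2)
        assert fr.nll <= chance
        assert fr.nll >= chance * 0.99  # no structure to exploit

    def test_decay_on_decayless_data_costs_one_penalty_unit(self, value_schedule,
                                                            reward_schedule):
        pv = rl.ParamVector(w_object=6.0, bias=0.0, alpha_reward=0.4,
                            alpha_unreward=0.3, decay=0.0)
        agent = agents.GeneratingValueAgent("object", pv, decay=True, seed=21)
        log = agents.simulate_value_agent(value_schedule, reward_schedule, agent)
        plain = rl.fit(log, rl.ModelSpec("object", False), seed=31)
        decayed = rl.fit(log, rl.ModelSpec("object", True), seed=32)
        # nested model: no structural likelihood gain available, so the BIC
        # difference is the extra-parameter penalty ln(N) minus at most a
        # small chance overfit (one spurious df gains ~chi2/2 of NLL)
        gain = plain.nll - decayed.nll
        assert -1e-3 <= gain < 3.0
        delta = decayed.bic - plain.bic
        assert delta <= math.log(336) + 2e-3
        assert delta == pytest.approx(math.log(336) - 2 * gain, abs=2e-3)
        assert delta > 0  # decay never pays for itself on decayless data


class TestComparison:
    def test_log_feature_weights_values_and_floor(self, value_log):
        fr = rl.fit(value_log, FEATURE_DECAY, seed=5)
        lw = rl.log_feature_weights(fr)
        p = fr.params
        for val, w in zip(lw, (p.w_leg, p.w_antennae, p.w_mandible)):
            assert val == pytest.approx(math.log(max(w, 1e-6)))
        assert all(v >= math.log(1e-6) for v in lw)
        pv = rl.ParamVector(w_leg=1.0, w_antennae=math.e, w_mandible=0.0,
                            alpha_reward=0.1, alpha_unreward=0.1, decay=0.1)
        fr2 = rl.FitResult(FEATURE_DECAY, pv, 0.0, np.zeros(1), 0.0, np.zeros(1),
                           1, True, 0, 0)
        assert rl.log_feature_weights(fr2) == pytest.approx((0.0, 1.0, math.log(1e-6)))

    def test_compare_models_table_and_contrast(self, value_schedule, reward_schedule):
        cohort = agents.generating_value_cohort(6, "feature", seed=77)
        fits = {}
        for i, (_, log) in enumerate(cohort):
            fits[i] = {
                s.name: rl.fit(log, s, seed=300 + i)
                for s in (FEATURE_DECAY, OBJECT_DECAY)
            }
        cmp_ = rl.compare_models(fits, contrasts=[("feature+decay", "object+decay")])
        assert cmp_["best_model"] == "feature+decay"
        diff = cmp_["contrasts"]["feature+decay - object+decay"]
        assert diff["bic_diff_mean"] < 0
        assert "signed_rank_p" in diff

    def test_mismatched_agent_model_sets_rejected(self, value_log):
        fr = rl.fit(value_log, OBJECT_DECAY, seed=1)
        fits = {0: {"object+decay": fr}, 1: {"feature+decay": fr}}
        with pytest.raises(ValueError, match="mismatched"):
            rl.compare_models(fits)
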